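"""Incremental cost-utility analysis across strategies.

ICERs are reported numerically even in dominance quadrants (a negative
ICER is sign-ambiguous on its own, so every comparison also carries a
dominance classification); decisions at a willingness-to-pay threshold are
taken on net monetary benefit, NMB = WTP x QALYs - cost, which is
well-behaved in all four quadrants of the cost-effectiveness plane.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd
from scipy.optimize import bisect

from .economics import StrategyOutcome
from .params import ModelConfig, evaluate_all

__all__ = ["WTPThreshold", "ComparisonResult", "icer", "nmb", "comparison_table", "threshold_price"]


@dataclass(frozen=True)
class WTPThreshold:
    """Willingness-to-pay threshold in yuan per QALY."""

    value: float = 287_391.0

    def __post_init__(self) -> None:
        if self.value <= 0:
            raise ValueError(f"WTP must be positive, got {self.value}")


@dataclass(frozen=True)
class ComparisonResult:
    """Pairwise incremental comparison, comparator minus reference."""

    reference: str
    comparator: str
    delta_cost: float
    delta_effect: float
    icer: float | None  # None when delta_effect == 0
    classification: str


def icer(
    a: StrategyOutcome, b: StrategyOutcome, wtp: WTPThreshold | float = WTPThreshold()
) -> ComparisonResult:
    """Incremental comparison of ``b`` (comparator) against ``a`` (reference).

    Classification: ``dominant`` (b cheaper and more effective),
    ``dominated`` (b dearer and less effective), ``indifferent`` (identical
    outcomes), otherwise cost-effective or not by the NMB rule at the WTP.
    """
    wtp_value = wtp.value if isinstance(wtp, WTPThreshold) else float(wtp)
    dc = b.total_cost - a.total_cost
    dq = b.total_qalys - a.total_qalys
    ratio = dc / dq if dq != 0 else None

    if dc == 0 and dq == 0:
        cls = "indifferent"
    elif dc <= 0 and dq >= 0:
        cls = "dominant"
    elif dc >= 0 and dq <= 0:
        cls = "dominated"
    elif wtp_value * dq - dc > 0:
        cls = "cost_effective_at_wtp"
    else:
        cls = "not_cost_effective_at_wtp"
    return ComparisonResult(
        reference=a.name, comparator=b.name,
        delta_cost=dc, delta_effect=dq, icer=ratio, classification=cls,
    )


def nmb(outcome: StrategyOutcome, wtp: WTPThreshold | float = WTPThreshold()) -> float:
    """Net monetary benefit, WTP x QALYs - cost (yuan)."""
    wtp_value = wtp.value if isinstance(wtp, WTPThreshold) else float(wtp)
    return wtp_value * outcome.total_qalys - outcome.total_cost


def comparison_table(
    outcomes: dict[str, StrategyOutcome], wtp: WTPThreshold | float = WTPThreshold()
) -> pd.DataFrame:
    """All ordered pairwise comparisons as a flat table."""
    rows = []
    for ref in outcomes:
        for comp in outcomes:
            if ref == comp:
                continue
            r = icer(outcomes[ref], outcomes[comp], wtp)
            rows.append(
                {
                    "reference": ref, "comparator": comp,
                    "cost_ref": outcomes[ref].total_cost,
                    "qaly_ref": outcomes[ref].total_qalys,
                    "cost_comp": outcomes[comp].total_cost,
                    "qaly_comp": outcomes[comp].total_qalys,
                    "delta_cost": r.delta_cost, "delta_qaly": r.delta_effect,
                    "icer": r.icer, "classification": r.classification,
                }
            )
    return pd.DataFrame(rows)


class BracketError(ValueError):
    """No ICER = WTP crossing inside the search bracket."""


def threshold_price(
    cfg: ModelConfig,
    target_param: str,
    comparison: tuple[str, str],
    wtp: WTPThreshold | float | None = None,
    bracket: tuple[float, float] | None = None,
    rtol: float = 1e-6,
) -> float:
    """Parameter value at which a pairwise ICER equals the WTP, by bisection.

    ``comparison`` is (reference, comparator); the ICER is for comparator vs
    reference.  The default bracket spans the parameter's registry bounds
    widened to 4x baseline, which covers the price ranges of interest.
    """
    if target_param not in cfg.parameters:
        raise KeyError(f"unknown parameter {target_param!r}")
    ref, comp = comparison
    wtp_value = cfg.wtp if wtp is None else (wtp.value if isinstance(wtp, WTPThreshold) else float(wtp))
    spec = cfg.parameters[target_param]
    if bracket is None:
        bracket = (0.0, max(4.0 * abs(spec.baseline), spec.high))

    def gap(x: float) -> float:
        out = evaluate_all(cfg, {target_param: x})
        r = icer(out[ref], out[comp], wtp_value)
        if r.icer is None:
            raise BracketError(
                f"delta QALYs is zero at {target_param}={x}; ICER undefined"
            )
        return r.icer - wtp_value

    lo, hi = bracket
    g_lo, g_hi = gap(lo), gap(hi)
    if g_lo == 0:
        return lo
    if g_hi == 0:
        return hi
    if g_lo * g_hi > 0:
        raise BracketError(
            f"ICER - WTP has the same sign at both bracket ends: "
            f"ICER({lo})={g_lo + wtp_value:,.0f}, ICER({hi})={g_hi + wtp_value:,.0f}, "
            f"WTP={wtp_value:,.0f}"
        )
    return float(bisect(gap, lo, hi, rtol=rtol, xtol=1e-9 * max(1.0, hi)))
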