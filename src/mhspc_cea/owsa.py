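"""One-way deterministic sensitivity analysis (tornado tables).

Each registry parameter is pushed to its lower and upper bound with all
other parameters at baseline, and the pairwise ICER is re-evaluated.  Rows
are ranked by the ICER span |icer_high - icer_low|.  Because an ICER span
is uninterpretable when the comparison changes dominance quadrant inside
the bar, the NMB-difference endpoints (comparator minus reference) are
reported alongside.

Bounds follow the source table: hazard ratios and utilities use their
published 95% CI, healthcare-service prices their institutional-tier
bounds, and every bound pair that is a rounded +/-20% of baseline is
regenerated exactly from the baseline to avoid rounding drift.
"""

from __future__ import annotations

from dataclasses import dataclass

import pandas as pd

from .cea import WTPThreshold, icer, nmb
from .params import ModelConfig, evaluate_all

__all__ = ["ParameterRange", "default_ranges", "owsa_run"]


@dataclass(frozen=True)
class ParameterRange:
    """One tornado bar: parameter bounds and the rule that produced them."""

    parameter: str
    baseline: float
    low: float
    high: float
    rule: str = "ci95"  # ci95 | pct20 | tier_prices

    def __post_init__(self) -> None:
        if not self.low <= self.baseline <= self.high:
            raise ValueError(
                f"{self.parameter}: range must satisfy low <= baseline <= high, "
                f"got ({self.low}, {self.baseline}, {self.high})"
            )
        if self.rule == "pct20":
            lo_exp, hi_exp = sorted((0.8 * self.baseline, 1.2 * self.baseline))
            if abs(self.low - lo_exp) > 1e-9 or abs(self.high - hi_exp) > 1e-9:
                raise ValueError(f"{self.parameter}: pct20 rule requires bounds 0.8x/1.2x baseline")


def _is_pct20(baseline: float, low: float, high: float) -> bool:
    if baseline == 0:
        return False
    lo_exp, hi_exp = sorted((0.8 * baseline, 1.2 * baseline))
    tol = 5e-4 * abs(baseline)
    return abs(low - lo_exp) <= tol and abs(high - hi_exp) <= tol


def default_ranges(cfg: ModelConfig) -> list[ParameterRange]:
    """Tornado ranges for every registry parameter.

    +/-20% bound pairs are regenerated exactly from the baseline; all other
    bounds are used as printed (95% CI for HRs and utilities,
    institutional-tier prices for imaging).
    """
    out = []
    for key, spec in cfg.parameters.items():
        if _is_pct20(spec.baseline, spec.low, spec.high):
            lo, hi = sorted((0.8 * spec.baseline, 1.2 * spec.baseline))
            rule = "pct20"
        else:
            lo, hi, rule = spec.low, spec.high, "ci95"
            if key == "cost_followup_imaging":
                rule = "tier_prices"
        out.append(ParameterRange(parameter=key, baseline=spec.baseline, low=lo, high=hi, rule=rule))
    return out


def owsa_run(
    cfg: ModelConfig,
    comparison: tuple[str, str],
    ranges: list[ParameterRange] | None = None,
    wtp: WTPThreshold | float | None = None,
) -> pd.DataFrame:
    """Tornado table for one strategy pair (reference, comparator).

    Returns one row per parameter with the ICER and NMB-difference at each
    bound, sorted by descending ICER span (ties and undefined spans last,
    alphabetical within ties).  The base-case ICER is repeated in
    ``icer_base`` for reference.
    """
    ref, comp = comparison
    wtp_value = cfg.wtp if wtp is None else (wtp.value if isinstance(wtp, WTPThreshold) else float(wtp))
    if ranges is None:
        ranges = default_ranges(cfg)
    for r in ranges:
        if r.parameter not in cfg.parameters:
            raise KeyError(f"unknown parameter {r.parameter!r} in OWSA ranges")

    base_out = evaluate_all(cfg)
    base = icer(base_out[ref], base_out[comp], wtp_value)

    rows = []
    for r in ranges:
        endpoints = {}
        for side, value in (("low", r.low), ("high", r.high)):
            out = (
                base_out
                if value == r.baseline
                else evaluate_all(cfg, {r.parameter: value})
            )
            res = icer(out[ref], out[comp], wtp_value)
            endpoints[side] = (
                res.icer,
                nmb(out[comp], wtp_value) - nmb(out[ref], wtp_value),
                res.classification,
            )
        il, ih = endpoints["low"][0], endpoints["high"][0]
        span = abs(ih - il) if il is not None and ih is not None else float("nan")
        rows.append(
            {
                "parameter": r.parameter,
                "rule": r.rule,
                "low": r.low,
                "high": r.high,
                "icer_at_low": il,
                "icer_at_high": ih,
                "nmb_diff_at_low": endpoints["low"][1],
                "nmb_diff_at_high": endpoints["high"][1],
                "span": span,
                "crosses_quadrant": endpoints["low"][2] != endpoints["high"][2],
                "icer_base": base.icer,
            }
        )
    table = pd.DataFrame(rows)
    table["_key"] = table["span"].fillna(-1.0)
    table = (
        table.sort_values(["_key", "parameter"], ascending=[False, True])
        .drop(columns="_key")
        .reset_index(drop=True)
    )
    table["rank"] = table.index + 1
    return table
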