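"""Costs and QALYs for one treatment strategy.

Direct medical costs only: first-line drug + ADT while progression-free,
the trial-reported subsequent-treatment mixture after progression,
per-cycle follow-up (laboratory + imaging) in both alive states,
supportive care, grade >=3 adverse-event management (expected cost charged
once at model entry), and a one-time end-of-life cost per incident death.
Utilities: the rPFS utility is lowered by the incidence-weighted AE
disutilities for the whole pre-progression duration; the PD utility is
used unadjusted.

Accrual rules the source tables leave open (which alive states accrue
supportive care, the discounting flags) are resolved by calibration against
the published arm-level totals; see docs/methods.md.  The calibrated
baseline accrues supportive care in both alive states
(``supportive_states="all_alive"``); ``"pd_only"`` is the alternative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np

from .cohort import CohortTrace, ModelSettings, discount_factor, half_cycle_occupancy, run_trace
from .survival import WeibullSurvival

__all__ = [
    "AdverseEvent",
    "SubsequentTreatment",
    "StrategyInputs",
    "StrategyOutcome",
    "cycle_cost",
    "cycle_utility",
    "one_time_costs",
    "evaluate_strategy",
]

STATES = ("rPFS", "PD")


@dataclass(frozen=True)
class AdverseEvent:
    """One grade >=3 adverse event: incidence, unit management cost, disutility."""

    label: str
    incidence: float
    unit_cost: float = 0.0
    disutility: float = 0.0  # non-positive utility decrement

    def __post_init__(self) -> None:
        if not 0 <= self.incidence <= 1:
            raise ValueError(f"{self.label}: incidence must be in [0, 1], got {self.incidence}")
        if self.unit_cost < 0:
            raise ValueError(f"{self.label}: unit cost must be >= 0")
        if self.disutility > 0:
            raise ValueError(f"{self.label}: disutility must be <= 0, got {self.disutility}")


@dataclass(frozen=True)
class SubsequentTreatment:
    """One post-progression regimen with its uptake proportion."""

    label: str
    proportion: float
    cost_per_cycle: float

    def __post_init__(self) -> None:
        if not 0 <= self.proportion <= 1:
            raise ValueError(f"{self.label}: proportion must be in [0, 1]")
        if self.cost_per_cycle < 0:
            raise ValueError(f"{self.label}: cost must be >= 0")


@dataclass(frozen=True)
class StrategyInputs:
    """One arm's full economic profile (all monetary values 2024 CNY)."""

    name: str
    firstline_drug_cost_per_cycle: float
    adt_cost_per_cycle: float
    ae_profile: tuple[AdverseEvent, ...]
    subsequent_mix: tuple[SubsequentTreatment, ...]
    followup_lab_cost: float
    followup_imaging_cost: float
    supportive_cost: float
    end_of_life_cost: float
    u_rpfs: float
    u_pd: float
    supportive_states: str = "all_alive"  # or "pd_only"

    def __post_init__(self) -> None:
        for fname in (
            "firstline_drug_cost_per_cycle",
            "adt_cost_per_cycle",
            "followup_lab_cost",
            "followup_imaging_cost",
            "supportive_cost",
            "end_of_life_cost",
        ):
            if getattr(self, fname) < 0:
                raise ValueError(f"{self.name}: {fname} must be >= 0")
        for uname in ("u_rpfs", "u_pd"):
            u = getattr(self, uname)
            if not 0 <= u <= 1:
                raise ValueError(f"{self.name}: {uname} must be in [0, 1], got {u}")
        if sum(s.proportion for s in self.subsequent_mix) > 1 + 1e-9:
            raise ValueError(f"{self.name}: subsequent-treatment proportions exceed 1")
        if self.supportive_states not in ("all_alive", "pd_only"):
            raise ValueError(f"{self.name}: unknown supportive_states {self.supportive_states!r}")


@dataclass(frozen=True)
class StrategyOutcome:
    """Totals for one arm, discounted per the settings, with undiscounted twins."""

    name: str
    total_cost: float
    total_qalys: float
    undiscounted_cost: float
    undiscounted_qalys: float
    cost_breakdown: dict[str, float] = field(default_factory=dict)


def cycle_cost(inputs: StrategyInputs, state: str, cycle: int = 1) -> float:
    """Cost accrued per cycle per unit of effective occupancy of ``state``.

    rPFS: first-line drug + ADT + follow-up (lab + imaging), plus supportive
    care when it accrues in all alive states.  PD: the proportion-weighted
    subsequent-treatment mixture + follow-up + supportive care.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    followup = inputs.followup_lab_cost + inputs.followup_imaging_cost
    if state == "rPFS":
        total = inputs.firstline_drug_cost_per_cycle + inputs.adt_cost_per_cycle + followup
        if inputs.supportive_states == "all_alive":
            total += inputs.supportive_cost
        return total
    subsq = sum(s.proportion * s.cost_per_cycle for s in inputs.subsequent_mix)
    return subsq + followup + inputs.supportive_cost


def cycle_utility(inputs: StrategyInputs, state: str) -> float:
    """Per-cycle utility weight of a state.

    The rPFS utility carries the incidence-weighted AE disutility for the
    whole pre-progression duration; PD is unadjusted.  A (pathological)
    negative adjusted utility is clamped to 0 with a warning.
    """
    if state not in STATES:
        raise ValueError(f"unknown state {state!r}; expected one of {STATES}")
    if state == "PD":
        return inputs.u_pd
    u = inputs.u_rpfs - sum(ae.incidence * abs(ae.disutility) for ae in inputs.ae_profile)
    if u < 0:
        warnings.warn(f"{inputs.name}: adjusted rPFS utility {u:.4f} < 0; clamped to 0")
        u = 0.0
    return u


def one_time_costs(
    inputs: StrategyInputs, trace: CohortTrace, settings: ModelSettings
) -> dict[str, float]:
    """Non-per-cycle cost components (discounted per the settings).

    AE management: expected cost sum(incidence x unit cost), charged once to
    the full cohort at model entry (time 0, so never discounted).
    End of life: one-time cost per incident death, discounted at the midpoint
    of the death cycle.  Returns the discounted components plus the
    undiscounted end-of-life twin.
    """
    ae = sum(a.incidence * a.unit_cost for a in inputs.ae_profile)
    k = np.arange(1, trace.n_cycles + 1)
    df = discount_factor(settings, k - 0.5) if settings.discount_costs else np.ones(k.size)
    eol = inputs.end_of_life_cost * float(np.sum(trace.new_deaths[1:] * df))
    eol_undisc = inputs.end_of_life_cost * float(np.sum(trace.new_deaths[1:]))
    return {"ae_management": ae, "end_of_life": eol, "end_of_life_undiscounted": eol_undisc}


def evaluate_strategy(
    inputs: StrategyInputs,
    pfs: WeibullSurvival,
    os: WeibullSurvival,
    settings: ModelSettings | None = None,
    trace: CohortTrace | None = None,
) -> StrategyOutcome:
    """Run the trace and accumulate discounted costs and QALYs for one arm."""
    settings = settings or ModelSettings()
    if trace is None:
        trace = run_trace(pfs, os, settings)
    eff = half_cycle_occupancy(trace)
    k = np.arange(1, trace.n_cycles + 1)
    mid_df = discount_factor(settings, k - 0.5)
    df_cost = mid_df if settings.discount_costs else np.ones(k.size)
    df_qaly = mid_df if settings.discount_qalys else np.ones(k.size)

    rpfs_cycles_disc = float(np.sum(eff["rpfs"] * df_cost))
    pd_cycles_disc = float(np.sum(eff["pd"] * df_cost))
    rpfs_cycles = float(np.sum(eff["rpfs"]))
    pd_cycles = float(np.sum(eff["pd"]))

    followup = inputs.followup_lab_cost + inputs.followup_imaging_cost
    subsq = sum(s.proportion * s.cost_per_cycle for s in inputs.subsequent_mix)
    supp_rpfs = inputs.supportive_cost if inputs.supportive_states == "all_alive" else 0.0

    onetime = one_time_costs(inputs, trace, settings)
    breakdown = {
        "first_line_drug": inputs.firstline_drug_cost_per_cycle * rpfs_cycles_disc,
        "adt": inputs.adt_cost_per_cycle * rpfs_cycles_disc,
        "followup": followup * (rpfs_cycles_disc + pd_cycles_disc),
        "supportive": supp_rpfs * rpfs_cycles_disc + inputs.supportive_cost * pd_cycles_disc,
        "subsequent_treatment": subsq * pd_cycles_disc,
        "ae_management": onetime["ae_management"],
        "end_of_life": onetime["end_of_life"],
    }
    total_cost = float(sum(breakdown.values()))
    undisc_cost = float(
        cycle_cost(inputs, "rPFS") * rpfs_cycles
        + cycle_cost(inputs, "PD") * pd_cycles
        + onetime["ae_management"]
        + onetime["end_of_life_undiscounted"]
    )

    u_rpfs, u_pd = cycle_utility(inputs, "rPFS"), cycle_utility(inputs, "PD")
    ypc = settings.years_per_cycle
    total_qalys = float(np.sum((eff["rpfs"] * u_rpfs + eff["pd"] * u_pd) * ypc * df_qaly))
    undisc_qalys = float((rpfs_cycles * u_rpfs + pd_cycles * u_pd) * ypc)

    return StrategyOutcome(
        name=inputs.name,
        total_cost=total_cost,
        total_qalys=total_qalys,
        undiscounted_cost=undisc_cost,
        undiscounted_qalys=undisc_qalys,
        cost_breakdown=breakdown,
    )
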