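"""Synthetic digitized-curve artifacts from known Weibull parameters.

The published-figure extraction stage (hand-digitized Kaplan-Meier curves
plus number-at-risk rows) cannot be re-run without the original figures, so
this module generates equivalent artifacts from a known ground truth:
individual event times are drawn from S(t) = exp(-lambda t^gamma) by
inverse CDF, optionally censored administratively (uniform accrual up to a
fixed follow-up cutoff), and the resulting Kaplan-Meier estimate is read
off on a reporting grid exactly as a digitizer would.  The reconstruction
and fitting stage can then be validated end to end against the generating
parameters.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .survival import DigitizedKM, ReconstructedIPD, SurvivalInputError, WeibullSurvival

__all__ = ["SimulationSpec", "simulate_ipd", "digitize", "write_digitized_km"]


@dataclass(frozen=True)
class SimulationSpec:
    """Ground truth and reporting layout for one synthetic curve.

    ``censoring`` is "none" or "uniform_admin" (patients accrue uniformly
    over ``accrual_window`` cycles and are administratively censored at
    ``followup_cutoff`` cycles after study start).  ``reporting_grid`` and
    ``risk_report_times`` are the digitized time points and the
    number-at-risk row times, in cycles.  ``jitter`` adds zero-mean uniform
    digitization noise of that half-width to the survival reads (default
    off, so round trips are exact up to KM step resolution).
    """

    curve: WeibullSurvival
    n_patients: int
    censoring: str = "none"
    accrual_window: float = 12.0
    followup_cutoff: float = 120.0
    reporting_grid: tuple[float, ...] = tuple(float(t) for t in range(0, 121, 2))
    risk_report_times: tuple[float, ...] = tuple(float(t) for t in range(0, 121, 12))
    seed: int = 0
    jitter: float = 0.0

    def __post_init__(self) -> None:
        if self.n_patients < 10:
            raise SurvivalInputError(f"n_patients must be >= 10, got {self.n_patients}")
        if self.censoring not in ("none", "uniform_admin"):
            raise SurvivalInputError(f"unknown censoring scheme {self.censoring!r}")
        if self.curve.scale <= 0:
            raise SurvivalInputError("simulation requires a positive scale (non-zero hazard)")
        grid = np.asarray(self.reporting_grid, dtype=float)
        if grid[0] != 0 or np.any(np.diff(grid) <= 0):
            raise SurvivalInputError("reporting_grid must start at 0 and increase strictly")
        if self.censoring == "uniform_admin":
            if not 0 <= self.accrual_window < self.followup_cutoff:
                raise SurvivalInputError("need 0 <= accrual_window < followup_cutoff")
            if grid[-1] > self.followup_cutoff:
                raise SurvivalInputError("reporting_grid extends past the administrative cutoff")
        if self.jitter < 0:
            raise SurvivalInputError("jitter must be >= 0")


def simulate_ipd(spec: SimulationSpec) -> ReconstructedIPD:
    """Draw (time, event) records from the spec's Weibull ground truth.

    Event times by inverse CDF: T = (-ln U / lambda)^(1/gamma).  Under
    administrative censoring each patient's follow-up is cutoff - entry,
    with entry uniform on [0, accrual_window]; times are on the follow-up
    clock (time since the patient's own entry).
    """
    rng = np.random.default_rng(spec.seed)
    gamma, lam = spec.curve.shape, spec.curve.scale
    u = rng.random(spec.n_patients)
    t_event = (-np.log(u) / lam) ** (1.0 / gamma)
    if spec.censoring == "none":
        return ReconstructedIPD(time=t_event, event=np.ones(spec.n_patients, dtype=int))
    entry = rng.random(spec.n_patients) * spec.accrual_window
    followup = spec.followup_cutoff - entry
    observed = np.minimum(t_event, followup)
    event = (t_event <= followup).astype(int)
    return ReconstructedIPD(time=observed, event=event)


def digitize(ipd: ReconstructedIPD, spec: SimulationSpec) -> DigitizedKM:
    """Read the Kaplan-Meier estimate of ``ipd`` off the reporting grid.

    Survival values are the KM step function evaluated at the grid times;
    numbers at risk count patients with observed time >= each risk-report
    time.  With ``jitter`` > 0, uniform digitization noise is added and the
    curve re-monotonized (as a careful digitizer would).
    """
    from lifelines import KaplanMeierFitter

    if ipd.n == 0:
        raise SurvivalInputError("cannot digitize an empty dataset")
    grid = np.asarray(spec.reporting_grid, dtype=float)
    if grid[-1] > float(ipd.time.max()) + 1e-12 and spec.censoring == "none":
        raise SurvivalInputError(
            f"reporting grid extends to {grid[-1]} beyond the last observed time "
            f"{ipd.time.max():.3f}"
        )
    km = KaplanMeierFitter().fit(ipd.time, ipd.event)
    surv = km.survival_function_at_times(grid).to_numpy()
    if spec.jitter > 0:
        rng = np.random.default_rng(spec.seed + 1)
        surv = surv + rng.uniform(-spec.jitter, spec.jitter, size=surv.size)
        surv = np.clip(np.minimum.accumulate(surv), 0.0, 1.0)
        surv[0] = 1.0
    risk_times = np.asarray(spec.risk_report_times, dtype=float)
    n_at_risk = np.array([(ipd.time >= t - 1e-12).sum() for t in risk_times], dtype=int)
    keep = n_at_risk > 0
    return DigitizedKM(
        times=grid,
        survival=surv,
        risk_times=risk_times[keep],
        numbers_at_risk=n_at_risk[keep],
    )


def write_digitized_km(km: DigitizedKM, out_prefix: str, truth: WeibullSurvival | None = None) -> list[str]:
    """Write the two-CSV digitized format (plus a ground-truth sidecar).

    Produces ``<prefix>_curve.csv`` (time, survival), ``<prefix>_risk.csv``
    (risk_time, n_at_risk) and, when the generating curve is known,
    ``<prefix>_truth.json`` for downstream recovery checks.
    """
    paths = []
    curve_path = f"{out_prefix}_curve.csv"
    pd.DataFrame({"time": km.times, "survival": km.survival}).to_csv(curve_path, index=False)
    paths.append(curve_path)
    risk_path = f"{out_prefix}_risk.csv"
    pd.DataFrame({"risk_time": km.risk_times, "n_at_risk": km.numbers_at_risk}).to_csv(
        risk_path, index=False
    )
    paths.append(risk_path)
    if truth is not None:
        truth_path = f"{out_prefix}_truth.json"
        with open(truth_path, "w") as fh:
            json.dump({"shape": truth.shape, "scale": truth.scale, "synthetic": True}, fh)
        paths.append(truth_path)
    return paths
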