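"""Parametric survival curves and transition probabilities.

The model works with Weibull survival functions in the parameterization

    S(t) = exp(-lambda * t**gamma)

with ``gamma`` the shape and ``lambda`` the scale, time measured in model
cycles (one cycle = 28 days).  Indirect comparisons are handled by scaling
the baseline (enzalutamide) hazard with a network-meta-analysis hazard
ratio: the comparator curve keeps the shape and multiplies the scale by the
HR point estimate.  Per-cycle transition probabilities follow from the
conditional survival ratio,

    tp(t, u) = 1 - S(t) / S(t - u) = 1 - exp(lambda*(t-u)**gamma - lambda*t**gamma).

The secondary path (digitized published curves -> pseudo individual patient
data -> Weibull fit) lives here as well, so the whole extrapolation stage
can be validated on synthetic curves with known parameters.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "WeibullSurvival",
    "HazardRatio",
    "DigitizedKM",
    "ReconstructedIPD",
    "FittedWeibull",
    "weibull_survival",
    "adjust_by_hr",
    "transition_probability",
    "fit_weibull",
    "reconstruct_ipd",
    "read_digitized_km",
    "write_curves",
]


class SurvivalInputError(ValueError):
    """Invalid argument to a survival-curve operation."""


class FittingError(RuntimeError):
    """Parametric fit could not be performed."""


@dataclass(frozen=True)
class WeibullSurvival:
    """One endpoint's Weibull survival curve, S(t) = exp(-scale * t**shape).

    Parameters
    ----------
    shape : float
        Weibull shape (gamma), > 0.
    scale : float
        Weibull scale (lambda), >= 0.  ``scale == 0`` is the zero-hazard
        degenerate curve S(t) = 1.
    time_unit : str
        Time unit of ``t``; the model uses 28-day cycles throughout.
    """

    shape: float
    scale: float
    time_unit: str = "cycle"

    def __post_init__(self) -> None:
        if not self.shape > 0:
            raise SurvivalInputError(f"shape must be > 0, got {self.shape}")
        if self.scale < 0:
            raise SurvivalInputError(f"scale must be >= 0, got {self.scale}")

    def survival(self, t):
        return weibull_survival(self, t)


@dataclass(frozen=True)
class HazardRatio:
    """Hazard ratio (comparator vs enzalutamide) with its 95% CI."""

    point: float
    ci_lower: float
    ci_upper: float
    endpoint: str  # "rPFS" or "OS"
    comparison: str = ""

    def __post_init__(self) -> None:
        if not (0 < self.ci_lower <= self.point <= self.ci_upper):
            raise SurvivalInputError(
                f"HR CI must satisfy 0 < lower <= point <= upper, got "
                f"({self.ci_lower}, {self.point}, {self.ci_upper})"
            )
        if self.endpoint not in ("rPFS", "OS"):
            raise SurvivalInputError(f"unknown endpoint {self.endpoint!r}")


def weibull_survival(curve: WeibullSurvival, t):
    """Survival probability S(t) = exp(-scale * t**shape) at time(s) ``t``.

    ``t`` is in the curve's time unit (model cycles).  Scalar or array.
    """
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise SurvivalInputError(f"t must be non-negative, got t={t}")
    out = np.exp(-curve.scale * np.power(t, curve.shape))
    return float(out) if out.ndim == 0 else out


def adjust_by_hr(base: WeibullSurvival, hr: HazardRatio, *, endpoint: str | None = None) -> WeibullSurvival:
    """Apply an indirect-comparison hazard ratio to the reference curve.

    The comparator keeps the reference shape; the scale is multiplied by the
    HR point estimate (proportional hazards on the Weibull scale).

    ``endpoint``, when given, must match ``hr.endpoint``; this guards against
    pairing an OS hazard ratio with an rPFS curve.
    """
    if endpoint is not None and endpoint != hr.endpoint:
        raise SurvivalInputError(
            f"endpoint mismatch: curve is {endpoint!r} but HR is for {hr.endpoint!r}"
        )
    return replace(base, scale=base.scale * hr.point)


def transition_probability(curve: WeibullSurvival, t: float, u: float) -> float:
    """Probability of the event during (t-u, t] conditional on surviving to t-u.

    tp(t, u) = 1 - exp(scale*(t-u)**shape - scale*t**shape), which equals
    1 - S(t)/S(t-u).  ``u`` is the cycle period; the engine calls this with
    u = 1 cycle and t = 1, 2, ... n_cycles.
    """
    if u <= 0:
        raise SurvivalInputError(f"u must be positive, got u={u}")
    if t < u:
        raise SurvivalInputError(f"t must be >= u, got t={t}, u={u}")
    expo = curve.scale * (t - u) ** curve.shape - curve.scale * t**curve.shape
    return -math.expm1(expo)


# ---------------------------------------------------------------------------
# Digitized curves and pseudo individual patient data
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class DigitizedKM:
    """A published Kaplan-Meier curve as read off the figure.

    ``times``/``survival`` are the digitized coordinates (with the (0, 1)
    anchor), ``risk_times``/``numbers_at_risk`` the number-at-risk row.
    """

    times: np.ndarray
    survival: np.ndarray
    risk_times: np.ndarray
    numbers_at_risk: np.ndarray

    def __post_init__(self) -> None:
        object.__setattr__(self, "times", np.asarray(self.times, dtype=float))
        object.__setattr__(self, "survival", np.asarray(self.survival, dtype=float))
        object.__setattr__(self, "risk_times", np.asarray(self.risk_times, dtype=float))
        object.__setattr__(self, "numbers_at_risk", np.asarray(self.numbers_at_risk, dtype=int))
        t, s = self.times, self.survival
        if t.size != s.size or t.size < 2:
            raise SurvivalInputError("times and survival must be equal-length, size >= 2")
        if t[0] != 0 or s[0] != 1.0:
            raise SurvivalInputError("digitized curve must start at (t=0, S=1)")
        if np.any(np.diff(t) <= 0):
            i = int(np.flatnonzero(np.diff(t) <= 0)[0]) + 1
            raise SurvivalInputError(f"times must be strictly increasing (index {i})")
        bad = np.flatnonzero(np.diff(s) > 1e-12)
        if bad.size:
            raise SurvivalInputError(f"survival increases at index {int(bad[0]) + 1}")
        if np.any((s < 0) | (s > 1)):
            raise SurvivalInputError("survival values must lie in [0, 1]")
        bad = np.flatnonzero(np.diff(self.numbers_at_risk) > 0)
        if bad.size:
            raise SurvivalInputError(
                f"numbers at risk increase at index {int(bad[0]) + 1}"
            )
        if np.any(self.numbers_at_risk < 0) or self.numbers_at_risk[0] <= 0:
            raise SurvivalInputError("numbers at risk must be positive at entry")


@dataclass(frozen=True)
class ReconstructedIPD:
    """Pseudo individual patient data: one (time, event) record per patient."""

    time: np.ndarray
    event: np.ndarray  # 1 = event, 0 = censored

    def __post_init__(self) -> None:
        object.__setattr__(self, "time", np.asarray(self.time, dtype=float))
        object.__setattr__(self, "event", np.asarray(self.event, dtype=int))
        if self.time.size != self.event.size:
            raise SurvivalInputError("time and event must have equal length")
        if np.any(self.time < 0):
            raise SurvivalInputError("times must be non-negative")
        if not np.isin(self.event, (0, 1)).all():
            raise SurvivalInputError("event flags must be 0 or 1")

    @property
    def n(self) -> int:
        return int(self.time.size)

    @property
    def n_events(self) -> int:
        return int(self.event.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"time": self.time, "event": self.event})


@dataclass(frozen=True)
class FittedWeibull:
    """MLE result: the fitted curve plus fit diagnostics."""

    curve: WeibullSurvival
    converged: bool
    log_likelihood: float
    n_events: int
    method: str = "mle"
    shape_ci: tuple[float, float] | None = None


def fit_weibull(ipd: ReconstructedIPD) -> FittedWeibull:
    """Maximum-likelihood Weibull fit with right censoring.

    Fits with :class:`lifelines.WeibullFitter` (parameterized as
    S(t) = exp(-(t/lambda_)**rho_)) and converts to the model's
    S(t) = exp(-scale * t**shape) with shape = rho_, scale = lambda_**(-rho_).
    Falls back to least squares on the complementary log-log of the
    Kaplan-Meier estimate if the MLE does not converge.
    """
    from lifelines import WeibullFitter

    if ipd.n_events == 0:
        raise FittingError("all records are censored; the Weibull scale is not identifiable")

    # lifelines rejects t == 0; nudge ties at zero to a negligible epsilon
    t = np.maximum(ipd.time, 1e-9)
    converged, wf = True, WeibullFitter()
    try:
        wf.fit(t, event_observed=ipd.event)
        shape = float(wf.rho_)
        scale = float(wf.lambda_) ** (-shape)
        loglik = float(wf.log_likelihood_)
        summ = wf.summary
        shape_ci = (
            float(summ.loc["rho_", "coef lower 95%"]),
            float(summ.loc["rho_", "coef upper 95%"]),
        )
        method = "mle"
    except Exception:
        converged = False
        shape, scale = _cloglog_fallback(ipd)
        loglik, shape_ci, method = float("nan"), None, "cloglog-ls"
    if ipd.n_events < 2:
        converged = False  # a single event cannot pin down both parameters
    return FittedWeibull(
        curve=WeibullSurvival(shape=shape, scale=scale),
        converged=converged,
        log_likelihood=loglik,
        n_events=ipd.n_events,
        method=method,
        shape_ci=shape_ci,
    )


def _cloglog_fallback(ipd: ReconstructedIPD) -> tuple[float, float]:
    """Least-squares line through log(-log S_KM(t)) vs log t."""
    from lifelines import KaplanMeierFitter

    km = KaplanMeierFitter().fit(np.maximum(ipd.time, 1e-9), ipd.event)
    sf = km.survival_function_.iloc[:, 0]
    mask = (sf.values > 0) & (sf.values < 1) & (sf.index.values > 0)
    if mask.sum() < 2:
        raise FittingError("too few distinct event times for the fallback fit")
    x = np.log(sf.index.values[mask])
    y = np.log(-np.log(sf.values[mask]))
    slope, intercept = np.polyfit(x, y, 1)
    return float(slope), float(np.exp(intercept))


def reconstruct_ipd(km: DigitizedKM) -> ReconstructedIPD:
    """Recover pseudo patient-level data from a digitized KM curve.

    Risk-set-anchored reconstruction in the style of Guyot et al.: within
    each interval between published numbers at risk, an integer number of
    censorings is found (spread evenly over the interval) such that walking
    the digitized survival steps with integer event counts reproduces the
    published number at risk at the start of the next interval; events are
    then placed at the digitized step times.  Patients still at risk after
    the last digitized time are censored there.
    """
    t, s = km.times, km.survival
    rt, nrisk = km.risk_times, km.numbers_at_risk
    K = t.size

    # interval j spans digitized indices with times in (rt[j], rt[j+1]]:
    # an event digitized at the boundary time has already left the risk set
    # counted there, so boundary steps belong to the earlier interval
    lower = np.searchsorted(t, rt, side="right")
    upper = np.append(lower[1:], K)

    event_times: list[float] = []
    censor_times: list[float] = []
    n_hat = float(nrisk[0])
    s_last = 1.0  # running KM estimate (at the most recent event time)

    for j in range(rt.size):
        lo, hi = int(lower[j]), int(upper[j])
        if lo >= hi:
            continue
        idx = np.arange(lo, hi)
        target_next = float(nrisk[j + 1]) if j + 1 < rt.size else None

        # initial censor count from the KM identity: without censoring the
        # risk set would shrink by the survival ratio across the interval
        if target_next is None:
            ncen = 0
        else:
            expected = n_hat * (s[hi - 1] / s_last if s_last > 0 else 0.0)
            ncen = max(0, int(round(expected - target_next)))
        best = None
        for _ in range(60):
            n_run, s_run = n_hat, s_last
            d_counts = np.zeros(idx.size, dtype=int)
            c_counts = _spread(ncen, idx.size)
            for m, k in enumerate(idx):
                if s_run > 0 and n_run > 0:
                    d = int(round(n_run * (1.0 - s[k] / s_run)))
                    d = min(max(d, 0), int(round(n_run)))
                else:
                    d = 0
                d_counts[m] = d
                if d > 0:
                    s_run = s_run * (1.0 - d / n_run)
                n_run -= d + c_counts[m]
            if target_next is None:
                # no later risk number anchors this tail: iterate the censor
                # count to the fixpoint where everyone not experiencing a
                # digitized event is censored *within* the interval (the
                # administrative-censoring reading), rather than heaped at
                # the last digitized time
                gap = int(round(n_run))
                if best is None or abs(gap) < abs(best[4]):
                    best = (d_counts, c_counts, 0.0, s_run, gap)
                if gap == 0:
                    break
                ncen = max(0, ncen + gap)
            else:
                gap = int(round(n_run - target_next))
                if best is None or abs(gap) < abs(best[4]):
                    best = (d_counts, c_counts, n_run, s_run, gap)
                if gap == 0:
                    break
                ncen = max(0, ncen + gap)
        d_counts, c_counts, n_hat, s_last = best[0], best[1], best[2], best[3]

        for m, k in enumerate(idx):
            # the digitized value at t[k] reflects events somewhere in
            # (t[k-1], t[k]]; the bracket midpoint is the least-biased
            # placement for a continuous event-time distribution
            t_lo = t[k - 1] if k > 0 else 0.0
            event_times.extend([0.5 * (t_lo + t[k])] * int(d_counts[m]))
            if c_counts[m] > 0:
                pos = t_lo + (np.arange(1, c_counts[m] + 1) / (c_counts[m] + 1)) * (t[k] - t_lo)
                censor_times.extend(pos.tolist())

    # whoever is left at the end of follow-up is administratively censored
    remaining = int(round(n_hat))
    if remaining > 0:
        censor_times.extend([float(t[-1])] * remaining)

    times = np.array(event_times + censor_times, dtype=float)
    events = np.array([1] * len(event_times) + [0] * len(censor_times), dtype=int)

    # conservation: exactly one record per patient initially at risk
    total = int(nrisk[0])
    if times.size > total:
        order = np.argsort(events)  # drop surplus censored records first
        keep = np.sort(order[times.size - total:])
        times, events = times[keep], events[keep]
    elif times.size < total:
        times = np.append(times, [float(t[-1])] * (total - times.size))
        events = np.append(events, [0] * (total - events.size))
    return ReconstructedIPD(time=times, event=events)


def _spread(total: int, bins: int) -> np.ndarray:
    """Distribute ``total`` integer counts as evenly as possible over ``bins``."""
    if bins <= 0:
        return np.zeros(0, dtype=int)
    base, extra = divmod(int(total), bins)
    out = np.full(bins, base, dtype=int)
    out[:extra] += 1
    return out


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_digitized_km(curve_csv, risk_csv) -> DigitizedKM:
    """Read the two-file digitized-curve format.

    ``curve_csv`` has columns (time, survival); ``risk_csv`` has columns
    (risk_time, n_at_risk).  Times are in model cycles.
    """
    curve = pd.read_csv(curve_csv)
    risk = pd.read_csv(risk_csv)
    return DigitizedKM(
        times=curve["time"].to_numpy(),
        survival=curve["survival"].to_numpy(),
        risk_times=risk["risk_time"].to_numpy(),
        numbers_at_risk=risk["n_at_risk"].to_numpy(),
    )


def write_curves(rows: Sequence[tuple[str, str, WeibullSurvival]], path) -> pd.DataFrame:
    """Write fitted/adjusted curves as CSV rows (arm, endpoint, shape, scale)."""
    frame = pd.DataFrame(
        [(arm, ep, c.shape, c.scale) for arm, ep, c in rows],
        columns=["arm", "endpoint", "shape", "scale"],
    )
    frame.to_csv(path, index=False)
    return frame
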