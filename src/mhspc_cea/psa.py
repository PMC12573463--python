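"""Probabilistic sensitivity analysis (second-order Monte Carlo).

Each uncertain parameter gets a sampling distribution derived from its
baseline and bounds by method of moments, treating the bounds as a 95%
interval (sd = range / 3.92): Gamma for costs, Beta for utilities and
probabilities (disutilities as Beta on the magnitude, then negated; the
discount rate as a Beta rescaled to its 0-8% support), Lognormal for
hazard ratios (log-mean = ln baseline, so the baseline is the median).
Every iteration draws one joint parameter vector - hazard-ratio draws
regenerate the comparator survival curves - and evaluates all three arms.
Results feed cost-effectiveness-plane scatter tables and acceptability
curves (CEAC), with the per-WTP winner defined by maximum net monetary
benefit and ties split equally.

Reproducibility: a single ``numpy.random.default_rng(seed)`` generator
draws all parameters in sorted registry-key order, so a seed pins the
whole analysis bitwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cea import WTPThreshold
from .params import ARMS, ModelConfig, evaluate_all

__all__ = ["DistributionSpec", "build_distribution", "default_distributions",
           "run_psa", "PSAResult", "ceac", "scatter_table"]

_CI_WIDTH = 3.92  # z_0.975 * 2: bounds treated as a 95% interval


@dataclass(frozen=True)
class DistributionSpec:
    """Sampling distribution for one parameter.

    ``derived_params`` holds the family-specific parameters; a spec with
    ``family == "degenerate"`` is a point mass at the baseline (used when
    the bounds collapse onto the baseline).
    """

    parameter: str
    family: str  # gamma | beta | lognormal | degenerate
    baseline: float
    low: float
    high: float
    derived_params: dict[str, float] = field(default_factory=dict)

    def sample(self, rng: np.random.Generator, n: int) -> np.ndarray:
        d = self.derived_params
        if self.family == "degenerate":
            return np.full(n, self.baseline)
        if self.family == "gamma":
            return rng.gamma(shape=d["shape"], scale=1.0 / d["rate"], size=n)
        if self.family == "beta":
            draws = rng.beta(d["alpha"], d["beta"], size=n) * d["support"]
            return -draws if d["negate"] else draws
        if self.family == "lognormal":
            return rng.lognormal(mean=d["log_mean"], sigma=d["log_sd"], size=n)
        raise ValueError(f"{self.parameter}: unknown family {self.family!r}")

    def mean(self) -> float:
        """Analytic mean (the lognormal returns its median, the anchor)."""
        if self.family == "lognormal":
            return math.exp(self.derived_params["log_mean"])
        return self.baseline


def build_distribution(
    parameter: str,
    family: str,
    baseline: float,
    low: float,
    high: float,
    support: float = 1.0,
) -> DistributionSpec:
    """Derive a sampling distribution from baseline + bounds.

    Gamma and Beta are moment-matched to mean = baseline and
    sd = (high - low) / 3.92; the Lognormal uses log-mean = ln(baseline),
    log-sd = (ln high - ln low) / 3.92.  ``support`` rescales the Beta to
    [0, support] (used for the discount rate's 0-8% range).  Negative
    baselines (disutilities) are modelled as Beta on the magnitude and
    negated on sampling.
    """
    if not low <= baseline <= high:
        raise ValueError(f"{parameter}: bounds must satisfy low <= baseline <= high")
    family = family.lower()
    sd = (high - low) / _CI_WIDTH
    if sd == 0:
        return DistributionSpec(parameter, "degenerate", baseline, low, high)

    if family == "gamma":
        if baseline <= 0:
            raise ValueError(f"{parameter}: gamma requires a positive baseline")
        shape = (baseline / sd) ** 2
        rate = baseline / sd**2
        return DistributionSpec(parameter, "gamma", baseline, low, high,
                                {"shape": shape, "rate": rate})

    if family == "beta":
        negate = baseline < 0
        m = abs(baseline)
        if negate and (low > 0 or high > 0):
            raise ValueError(f"{parameter}: negative baseline requires non-positive bounds")
        ms, ss = m / support, sd / support
        if not 0 < ms < 1:
            raise ValueError(
                f"{parameter}: beta mean {m} outside the (0, {support}) support"
            )
        if ss**2 >= ms * (1 - ms):
            raise ValueError(f"{parameter}: sd {sd} too large for a beta distribution")
        alpha = ms * (ms * (1 - ms) / ss**2 - 1)
        beta_ = alpha * (1 - ms) / ms
        return DistributionSpec(parameter, "beta", baseline, low, high,
                                {"alpha": alpha, "beta": beta_, "support": support,
                                 "negate": negate})

    if family == "lognormal":
        if baseline <= 0 or low <= 0:
            raise ValueError(f"{parameter}: lognormal requires positive baseline and bounds")
        return DistributionSpec(parameter, "lognormal", baseline, low, high,
                                {"log_mean": math.log(baseline),
                                 "log_sd": (math.log(high) - math.log(low)) / _CI_WIDTH})

    raise ValueError(f"{parameter}: unsupported family {family!r}")


def default_distributions(cfg: ModelConfig) -> dict[str, DistributionSpec]:
    """One spec per registry parameter, per its table distribution column."""
    out = {}
    for key, spec in cfg.parameters.items():
        support = 0.08 if key == "discount_rate" else 1.0
        if spec.distribution == "beta" and abs(spec.baseline) > support:
            support = 1.0
        out[key] = build_distribution(
            key, spec.distribution, spec.baseline, spec.low, spec.high, support=support
        )
    return out


@dataclass(frozen=True)
class PSAResult:
    """Per-iteration (strategy, cost, qalys) triples."""

    frame: pd.DataFrame  # columns: iteration, strategy, cost, qalys
    n_iter: int
    seed: int

    def wide(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(costs, qalys) as n_iter x n_strategies frames."""
        costs = self.frame.pivot(index="iteration", columns="strategy", values="cost")
        qalys = self.frame.pivot(index="iteration", columns="strategy", values="qalys")
        return costs, qalys


def run_psa(
    cfg: ModelConfig,
    n_iter: int | None = None,
    seed: int | None = None,
    specs: dict[str, DistributionSpec] | None = None,
) -> PSAResult:
    """Second-order Monte Carlo over the full parameter registry.

    Structural quantities (state structure, cycle count, the reference
    Weibull shapes/scales) are not sampled; comparator curves are rebuilt
    from each iteration's hazard-ratio draws.
    """
    n_iter = cfg.n_iter if n_iter is None else int(n_iter)
    if n_iter <= 0:
        raise ValueError(f"n_iter must be positive, got {n_iter}")
    seed = cfg.seed if seed is None else int(seed)
    if specs is None:
        specs = default_distributions(cfg)
    missing = set(cfg.parameters) - set(specs)
    if missing:
        raise ValueError(f"no sampling spec for parameters: {sorted(missing)}")

    rng = np.random.default_rng(seed)
    draws = {key: specs[key].sample(rng, n_iter) for key in sorted(specs)}

    records = []
    for i in range(n_iter):
        values = {key: float(draws[key][i]) for key in draws}
        outcomes = evaluate_all(cfg, values)
        for arm in ARMS:
            records.append((i, arm, outcomes[arm].total_cost, outcomes[arm].total_qalys))
    frame = pd.DataFrame(records, columns=["iteration", "strategy", "cost", "qalys"])
    return PSAResult(frame=frame, n_iter=n_iter, seed=seed)


def ceac(result: PSAResult, wtp_grid) -> pd.DataFrame:
    """Cost-effectiveness acceptability: P(strategy has max NMB) per WTP.

    Ties (within strict float equality) are split equally among the tied
    strategies, so the probabilities sum to 1 at every WTP.
    """
    wtp_grid = np.asarray(list(wtp_grid), dtype=float)
    if wtp_grid.size == 0:
        raise ValueError("wtp_grid must be non-empty")
    if result.frame.empty:
        raise ValueError("PSA result is empty")
    costs, qalys = result.wide()
    strategies = list(costs.columns)
    C, Q = costs.to_numpy(), qalys.to_numpy()
    rows = []
    for w in wtp_grid:
        nmb = w * Q - C
        best = nmb.max(axis=1, keepdims=True)
        winners = nmb == best
        share = winners / winners.sum(axis=1, keepdims=True)
        probs = share.mean(axis=0)
        for s, p in zip(strategies, probs):
            rows.append({"wtp": w, "strategy": s, "probability": float(p)})
    return pd.DataFrame(rows)


def scatter_table(result: PSAResult, reference: str) -> pd.DataFrame:
    """Per-iteration incremental (delta_qalys, delta_cost) vs a reference.

    One block of n_iter rows per strategy; the reference's own block is
    identically zero.
    """
    costs, qalys = result.wide()
    if reference not in costs.columns:
        raise KeyError(f"unknown reference strategy {reference!r}")
    rows = []
    for comp in costs.columns:
        rows.append(
            pd.DataFrame(
                {
                    "iteration": costs.index,
                    "comparator": comp,
                    "delta_qalys": qalys[comp] - qalys[reference],
                    "delta_cost": costs[comp] - costs[reference],
                }
            )
        )
    return pd.concat(rows, ignore_index=True)
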