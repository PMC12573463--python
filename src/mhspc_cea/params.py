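"""Parameter registry, packaged baseline tables, and model configuration.

The packaged CSVs under ``mhspc_cea/data`` transcribe the published model
inputs: Weibull survival parameters per arm and endpoint, grade >=3
adverse-event incidences and subsequent-treatment proportions per arm, and
the cost/utility/HR table with sensitivity bounds and sampling-distribution
families.  Every tunable scalar lives in a flat registry keyed by a stable
name (``cost_enzalutamide``, ``u_rpfs``, ``hr_os_dve``, ...), so the
deterministic analysis, the tornado analysis and the probabilistic analysis
all vary parameters through the same single entry point,
:func:`evaluate_all`.

Sign convention: disutility bounds are stored as signed numbers with
``lower <= baseline <= upper`` (the source table orders those two columns
by magnitude instead).
"""

from __future__ import annotations

import copy
import importlib.resources as resources
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
import yaml

from .cohort import ModelSettings
from .economics import AdverseEvent, StrategyInputs, SubsequentTreatment, evaluate_strategy
from .survival import HazardRatio, WeibullSurvival, adjust_by_hr

__all__ = [
    "ARMS",
    "ParamSpec",
    "ModelConfig",
    "load_tables",
    "default_config",
    "load_config",
    "save_config",
    "build_curves",
    "build_strategies",
    "evaluate_all",
]

ARMS = ("Enza_ADT", "Apa_ADT", "Dar_ADT")
WTP_DEFAULT = 287_391.0  # 3x 2024 Chinese per-capita GDP, yuan/QALY

AE_EVENTS = (
    "fatigue", "hypertension", "rash", "fracture", "anemia",
    "back_pain", "ast", "alt", "neutropenia",
)
SUBSEQUENT_REGIMENS = ("sl_docetaxel", "sl_abiraterone", "sl_enzalutamide", "sl_apalutamide")
HR_KEYS = {
    "Apa_ADT": {"rPFS": "hr_rpfs_ave", "OS": "hr_os_ave"},
    "Dar_ADT": {"rPFS": "hr_rpfs_dve", "OS": "hr_os_dve"},
}


class ConfigError(ValueError):
    """Invalid configuration content; the message names the offending key."""


@dataclass(frozen=True)
class ParamSpec:
    """Registry entry: baseline value, sensitivity bounds, PSA family."""

    key: str
    baseline: float
    low: float
    high: float
    distribution: str  # gamma | beta | lognormal
    label: str = ""

    def __post_init__(self) -> None:
        if not self.low <= self.baseline <= self.high:
            raise ConfigError(
                f"{self.key}: bounds must satisfy low <= baseline <= high, "
                f"got ({self.low}, {self.baseline}, {self.high})"
            )
        if self.distribution.lower() not in ("gamma", "beta", "lognormal"):
            raise ConfigError(f"{self.key}: unknown distribution {self.distribution!r}")


def _data_path(name: str):
    return resources.files("mhspc_cea.data").joinpath(name)


def load_tables() -> dict[str, pd.DataFrame]:
    """Load the packaged baseline tables as DataFrames."""
    out = {}
    for name in ("survival_parameters", "ae_incidence", "subsequent_treatment", "model_parameters"):
        with resources.as_file(_data_path(f"{name}.csv")) as p:
            out[name] = pd.read_csv(p)
    return out


@dataclass
class ModelConfig:
    """Fully resolved model configuration.

    ``parameters`` is the registry (key -> ParamSpec).  ``ae_incidence`` and
    ``subsequent_mix`` hold the per-arm trial proportions (fractions, not
    percent).  ``base_curves`` holds the reference (enzalutamide) Weibull
    parameters per endpoint; comparator curves are derived from the HR
    registry entries at evaluation time.
    """

    settings: ModelSettings
    parameters: dict[str, ParamSpec]
    ae_incidence: dict[str, dict[str, float]]      # arm -> event -> fraction
    subsequent_mix: dict[str, dict[str, float]]    # arm -> regimen -> fraction
    base_curves: dict[str, WeibullSurvival]        # endpoint -> enzalutamide curve
    wtp: float = WTP_DEFAULT
    seed: int = 20251016
    n_iter: int = 10_000
    wtp_grid: tuple[float, ...] = tuple(float(w) for w in range(0, 600_001, 25_000))
    supportive_states: str = "all_alive"
    output_dir: str = "outputs"

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        for arm in ARMS:
            if arm not in self.ae_incidence:
                raise ConfigError(f"ae_incidence: missing arm {arm}")
            if arm not in self.subsequent_mix:
                raise ConfigError(f"subsequent_mix: missing arm {arm}")
        for arm, mix in self.subsequent_mix.items():
            total = sum(mix.values())
            if total > 1 + 1e-9:
                raise ConfigError(f"subsequent_mix.{arm}: proportions sum to {total:.3f} > 1")
        for arm, inc in self.ae_incidence.items():
            for ev, v in inc.items():
                if not 0 <= v <= 1:
                    raise ConfigError(f"ae_incidence.{arm}.{ev}: {v} outside [0, 1]")
        for ukey in ("u_rpfs", "u_pd"):
            u = self.parameters[ukey].baseline
            if not 0 <= u <= 1:
                raise ConfigError(f"parameters.{ukey}.baseline: {u} outside [0, 1]")
        if self.wtp <= 0:
            raise ConfigError(f"wtp: must be positive, got {self.wtp}")
        for ep in ("rPFS", "OS"):
            if ep not in self.base_curves:
                raise ConfigError(f"base_curves: missing endpoint {ep}")

    # -- derived views -----------------------------------------------------

    def baseline_values(self) -> dict[str, float]:
        return {k: spec.baseline for k, spec in self.parameters.items()}

    def hazard_ratio(self, key: str) -> HazardRatio:
        spec = self.parameters[key]
        endpoint = "rPFS" if "rpfs" in key else "OS"
        return HazardRatio(
            point=spec.baseline, ci_lower=spec.low, ci_upper=spec.high,
            endpoint=endpoint, comparison=spec.label,
        )


# ---------------------------------------------------------------------------
# Defaults from the packaged tables
# ---------------------------------------------------------------------------


def default_config(**overrides) -> ModelConfig:
    """The packaged baseline configuration (calibrated defaults)."""
    tables = load_tables()

    params: dict[str, ParamSpec] = {}
    for _, row in tables["model_parameters"].iterrows():
        params[row["key"]] = ParamSpec(
            key=row["key"],
            baseline=float(row["Baseline values"]),
            low=float(row["Lower limits"]),
            high=float(row["Upper limits"]),
            distribution=str(row["Distribution"]).lower(),
            label=row["label"],
        )

    ae = tables["ae_incidence"].set_index("event")
    ae_incidence = {arm: (ae[arm] / 100.0).to_dict() for arm in ARMS}
    sub = tables["subsequent_treatment"].set_index("regimen")
    subsequent_mix = {arm: (sub[arm] / 100.0).to_dict() for arm in ARMS}

    surv = tables["survival_parameters"]
    enza = surv[surv["Treatment"] == "Enza_ADT"].set_index("Endpoint")
    base_curves = {
        ep: WeibullSurvival(
            shape=float(enza.loc[ep, "Shape parameter"]),
            scale=float(enza.loc[ep, "Scale parameter"]),
        )
        for ep in ("rPFS", "OS")
    }

    cfg = ModelConfig(
        settings=ModelSettings(),
        parameters=params,
        ae_incidence=ae_incidence,
        subsequent_mix=subsequent_mix,
        base_curves=base_curves,
    )
    return replace_config(cfg, **overrides) if overrides else cfg


def replace_config(cfg: ModelConfig, **overrides) -> ModelConfig:
    """Copy a config with top-level fields replaced."""
    new = copy.deepcopy(cfg)
    for k, v in overrides.items():
        if not hasattr(new, k):
            raise ConfigError(f"unknown config field {k!r}")
        setattr(new, k, v)
    new.validate()
    return new


# ---------------------------------------------------------------------------
# YAML user configs
# ---------------------------------------------------------------------------

_SETTINGS_FIELDS = (
    "cycle_length_days", "horizon_years", "annual_discount_rate",
    "half_cycle_correction", "discount_qalys", "discount_costs", "n_cycles",
)
_SCALAR_FIELDS = ("wtp", "seed", "n_iter", "supportive_states", "output_dir")


def load_config(path) -> ModelConfig:
    """Load a YAML config; unspecified keys fall back to the packaged defaults.

    Recognized keys: ``settings.<field>``, ``parameters.<key>.{baseline,low,
    high,distribution}``, ``wtp``, ``seed``, ``n_iter``, ``wtp_grid``,
    ``supportive_states``, ``output_dir``.  Unknown keys and bound
    violations are rejected with the offending key path.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("config root must be a mapping")
    cfg = default_config()

    known = {"settings", "parameters", "wtp_grid", *_SCALAR_FIELDS}
    for key in raw:
        if key not in known:
            raise ConfigError(f"unknown config key {key!r}")

    if "settings" in raw:
        sdict = {f: getattr(cfg.settings, f) for f in _SETTINGS_FIELDS}
        for k, v in (raw["settings"] or {}).items():
            if k not in sdict:
                raise ConfigError(f"settings.{k}: unknown setting")
            sdict[k] = v
        try:
            cfg.settings = ModelSettings(**sdict)
        except ValueError as e:
            raise ConfigError(f"settings: {e}") from e

    for key, patch in (raw.get("parameters") or {}).items():
        if key not in cfg.parameters:
            raise ConfigError(f"parameters.{key}: unknown parameter name")
        spec = cfg.parameters[key]
        fields = {"baseline": spec.baseline, "low": spec.low, "high": spec.high,
                  "distribution": spec.distribution}
        if isinstance(patch, Mapping):
            for f, v in patch.items():
                if f not in fields:
                    raise ConfigError(f"parameters.{key}.{f}: unknown field")
                fields[f] = v
        else:  # shorthand: a bare number moves the baseline (bounds follow if violated)
            fields["baseline"] = float(patch)
            fields["low"] = min(fields["low"], fields["baseline"])
            fields["high"] = max(fields["high"], fields["baseline"])
        try:
            cfg.parameters[key] = ParamSpec(key=key, label=spec.label, **fields)
        except ConfigError:
            raise
        except ValueError as e:
            raise ConfigError(f"parameters.{key}: {e}") from e

    for f in _SCALAR_FIELDS:
        if f in raw:
            setattr(cfg, f, raw[f])
    if "wtp_grid" in raw:
        cfg.wtp_grid = tuple(float(w) for w in raw["wtp_grid"])
    if not (0 <= cfg.parameters["u_rpfs"].baseline <= 1):
        raise ConfigError("parameters.u_rpfs.baseline: outside [0, 1]")
    cfg.validate()
    return cfg


def save_config(cfg: ModelConfig, path) -> None:
    """Serialize a config to YAML (round-trips through load_config)."""
    doc = {
        "settings": {f: getattr(cfg.settings, f) for f in _SETTINGS_FIELDS},
        "parameters": {
            k: {"baseline": s.baseline, "low": s.low, "high": s.high,
                "distribution": s.distribution}
            for k, s in cfg.parameters.items()
        },
        "wtp": cfg.wtp,
        "seed": cfg.seed,
        "n_iter": cfg.n_iter,
        "wtp_grid": list(cfg.wtp_grid),
        "supportive_states": cfg.supportive_states,
        "output_dir": cfg.output_dir,
    }
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=True)


# ---------------------------------------------------------------------------
# Building model objects from a parameter vector
# ---------------------------------------------------------------------------


def build_curves(
    cfg: ModelConfig, values: Mapping[str, float] | None = None
) -> dict[str, dict[str, WeibullSurvival]]:
    """Per-arm rPFS/OS curves; comparators via HR scaling of the reference."""
    v = dict(cfg.baseline_values())
    if values:
        v.update(values)
    out = {"Enza_ADT": dict(cfg.base_curves)}
    for arm, keys in HR_KEYS.items():
        out[arm] = {}
        for ep, hr_key in keys.items():
            spec = cfg.parameters[hr_key]
            hr = HazardRatio(
                point=v[hr_key],
                ci_lower=min(spec.low, v[hr_key]),
                ci_upper=max(spec.high, v[hr_key]),
                endpoint=ep,
                comparison=spec.label,
            )
            out[arm][ep] = adjust_by_hr(cfg.base_curves[ep], hr, endpoint=ep)
    return out


def build_strategies(
    cfg: ModelConfig, values: Mapping[str, float] | None = None
) -> dict[str, StrategyInputs]:
    """Per-arm StrategyInputs from the registry values (Tables 2-3)."""
    v = dict(cfg.baseline_values())
    if values:
        v.update(values)
    drug_key = {"Enza_ADT": "cost_enzalutamide", "Apa_ADT": "cost_apalutamide",
                "Dar_ADT": "cost_darolutamide"}
    out = {}
    for arm in ARMS:
        ae_profile = tuple(
            AdverseEvent(
                label=ev,
                incidence=cfg.ae_incidence[arm].get(ev, 0.0),
                unit_cost=v.get(f"cost_ae_{ev}", 0.0),
                disutility=v.get(f"disutil_{ev}", 0.0),
            )
            for ev in AE_EVENTS
            if cfg.ae_incidence[arm].get(ev, 0.0) > 0
        )
        mix = tuple(
            SubsequentTreatment(
                label=reg, proportion=cfg.subsequent_mix[arm].get(reg, 0.0),
                cost_per_cycle=v[f"cost_{reg}"],
            )
            for reg in SUBSEQUENT_REGIMENS
            if cfg.subsequent_mix[arm].get(reg, 0.0) > 0
        )
        out[arm] = StrategyInputs(
            name=arm,
            firstline_drug_cost_per_cycle=v[drug_key[arm]],
            adt_cost_per_cycle=v["cost_adt"],
            ae_profile=ae_profile,
            subsequent_mix=mix,
            followup_lab_cost=v["cost_followup_lab"],
            followup_imaging_cost=v["cost_followup_imaging"],
            supportive_cost=v["cost_supportive"],
            end_of_life_cost=v["cost_end_of_life"],
            u_rpfs=v["u_rpfs"],
            u_pd=v["u_pd"],
            supportive_states=cfg.supportive_states,
        )
    return out


def evaluate_all(
    cfg: ModelConfig,
    values: Mapping[str, float] | None = None,
    settings: ModelSettings | None = None,
):
    """Evaluate all three strategies for one parameter vector.

    ``values`` overrides registry baselines (the discount rate override is
    routed into the settings).  Returns {arm: StrategyOutcome}.
    """
    v = dict(cfg.baseline_values())
    if values:
        v.update(values)
    settings = settings or cfg.settings
    if v["discount_rate"] != settings.annual_discount_rate:
        settings = ModelSettings(
            cycle_length_days=settings.cycle_length_days,
            horizon_years=settings.horizon_years,
            annual_discount_rate=v["discount_rate"],
            half_cycle_correction=settings.half_cycle_correction,
            discount_qalys=settings.discount_qalys,
            discount_costs=settings.discount_costs,
            n_cycles=settings.n_cycles,
        )
    curves = build_curves(cfg, v)
    strategies = build_strategies(cfg, v)
    return {
        arm: evaluate_strategy(
            strategies[arm], curves[arm]["rPFS"], curves[arm]["OS"], settings
        )
        for arm in ARMS
    }
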