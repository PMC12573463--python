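# mhspc-cea

A Markov cohort cost-utility model comparing the three second-generation
androgen-receptor antagonists — **enzalutamide**, **apalutamide** and
**darolutamide**, each combined with androgen deprivation therapy (ADT) —
as first-line treatment of metastatic hormone-sensitive prostate cancer
(mHSPC), from the perspective of the Chinese healthcare system.

It is written for health-economics and HTA analysts who want a fully
scripted, testable re-implementation of a published three-state
cost-utility analysis: every parameter is in packaged CSV tables, every
result is reproducible from a config + seed, and the survival-curve
extrapolation stage can be validated end to end on synthetic data.

## The model

Three health states on a 28-day cycle over 15 years (195 cycles):

```
rPFS ──► PD ──► Death
  └──────────────┘
```

Survival is Weibull, S(t) = exp(−λ·t^γ) with t in cycles.  Comparator arms
are derived from the enzalutamide reference by indirect comparison: shared
shape γ, scale λ multiplied by the network-meta-analysis hazard ratio.
Per-cycle transition probabilities are dynamic,

    tp(t, u) = 1 − exp{λ(t−u)^γ − λt^γ} = 1 − S(t)/S(t−u),   u = 1 cycle,

with death (from the OS curve) applied to both alive states, so the
cohort's alive fraction reproduces the OS curve exactly.  Costs (drug, ADT,
follow-up, supportive care, subsequent treatment, adverse-event management,
end-of-life) and utilities (0.76 rPFS / 0.68 PD, AE-adjusted) accrue with
half-cycle correction; strategies are compared by ICER = ΔC/ΔQ and net
monetary benefit at a willingness-to-pay of 287,391 yuan/QALY.  One-way
(tornado) and probabilistic (10,000-draw Monte Carlo, CEAC) sensitivity
analyses are included.  See `docs/methods.md` for assumptions, calibration
decisions, and known limitations.

## Worked example

```python
from mhspc_cea import default_config, evaluate_all, icer

cfg = default_config()                 # packaged calibrated baseline
out = evaluate_all(cfg)
for arm, o in out.items():
    print(f"{arm:9s} cost {o.total_cost:11,.0f} yuan   {o.total_qalys:.3f} QALYs")

r = icer(out["Apa_ADT"], out["Dar_ADT"], cfg.wtp)
print(f"Dar vs Apa: dCost {r.delta_cost:,.0f}, dQALY {r.delta_effect:.3f}, "
      f"ICER {r.icer:,.0f} ({r.classification})")
```

prints

```
Enza_ADT  cost     958,754 yuan   4.799 QALYs
Apa_ADT   cost     813,555 yuan   4.831 QALYs
Dar_ADT   cost     723,238 yuan   4.256 QALYs
Dar vs Apa: dCost -90,317, dQALY -0.575, ICER 157,004 (not_cost_effective_at_wtp)
```

Reading: over 15 years the enzalutamide strategy is the most expensive
(≈959k yuan) for 4.80 QALYs; apalutamide costs ≈145k yuan less and yields
slightly more QALYs (so enzalutamide is dominated); darolutamide is the
cheapest but — because its modeled overall-survival hazard ratio (1.24) is
unfavourable — also the least effective, and at the 287,391 yuan/QALY
threshold the extra QALYs of apalutamide over darolutamide are worth their
extra cost (ICER 157k < WTP).  Note that the published analysis this model
re-implements reports darolutamide as dominant; that ordering is not
derivable from its own printed survival inputs — see
`docs/methods.md` ("A structural limitation of the published inputs").

The command-line interface exposes the same pipeline:

```bash
mhspc-cea --out outputs run            # outcomes + pairwise comparisons (CSV)
mhspc-cea --out outputs owsa --pair Apa_ADT,Enza_ADT
mhspc-cea --out outputs psa --n-iter 10000
mhspc-cea threshold-price --param cost_apalutamide --pair Apa_ADT,Enza_ADT
mhspc-cea simulate-km --shape 1.1314 --scale 0.0079 --n 500 --out-prefix km
```

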