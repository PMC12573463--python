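# Methods

## Decision problem and model structure

The package evaluates the cost-utility, from the perspective of the Chinese
healthcare system, of three second-generation androgen-receptor antagonists —
enzalutamide, apalutamide and darolutamide, each combined with androgen
deprivation therapy (ADT) — as first-line treatment of metastatic
hormone-sensitive prostate cancer (mHSPC).

The model is a three-state Markov cohort model:

* **rPFS** — radiographically progression-free, on first-line treatment;
* **PD** — progressive disease, first-line treatment stopped and a fixed
  subsequent-treatment mixture started;
* **Death** — absorbing.

Transitions are unidirectional (rPFS → PD → Death, rPFS → Death).  The cycle
length is 28 days (the ADT injection interval) and the horizon is 15 years,
i.e. `n_cycles = floor(15 × 365.25 / 28) = 195`.

## Survival inputs and transition probabilities

Each arm's rPFS and overall survival (OS) are Weibull curves in the
parameterization

    S(t) = exp(−λ t^γ),

with `t` in cycles.  The reference (enzalutamide) parameters are, per
endpoint, `(γ, λ) = (1.131400, 0.007900)` for rPFS and
`(1.426021, 0.001476)` for OS.  The comparators are obtained by indirect
comparison: the shape is shared and the scale is multiplied by the
network-meta-analysis hazard ratio versus enzalutamide (rPFS: 0.76
apalutamide, 0.85 darolutamide; OS: 0.99 apalutamide, 1.24 darolutamide).
The published parameter tables do not state the time unit of `(γ, λ)`; the
cycle-unit reading is adopted because it is the only one under which the
published arm-level QALY magnitudes are attainable.  The unit is
configurable on `WeibullSurvival`.

Per-cycle transition probabilities are the conditional event probabilities

    tp(t, u) = 1 − exp(λ (t−u)^γ − λ t^γ) = 1 − S(t) / S(t−u),

evaluated with `u = 1` cycle.  Each cycle applies the OS-based death
probability to *both* alive states and the residual progression probability
`max(0, tp_rPFS − tp_OS)` to rPFS.  This is the unique uniform-mortality
choice that makes the cohort's alive fraction reproduce the OS curve
exactly, so the input curves double as closed-form oracles for the engine
(tested to 1e−10).  For darolutamide the OS hazard overtakes the rPFS
hazard inside the horizon (a by-product of its OS hazard ratio of 1.24);
progression is then clamped at zero, PD occupancy stays non-negative, and a
small excess of rPFS occupancy above `S_rPFS` is tolerated in preference to
distorting the exact alive trace.

## Costs, utilities and accrual rules

All monetary values are 2024 CNY; only direct medical costs enter.
Per-cycle accrual per unit of (half-cycle-corrected) state occupancy:

* **rPFS**: first-line drug + ADT (905.61) + laboratory follow-up (782.13)
  + imaging follow-up (394.88) + supportive care (2255.87, see below);
* **PD**: incidence-weighted subsequent-treatment mixture (trial-reported
  proportions; the untreated remainder accrues no subsequent drug cost)
  + laboratory + imaging + supportive care.  Subsequent treatment continues
  until death (no third-line states).

One-time components: expected grade ≥3 adverse-event (AE) management cost
`Σ incidence × unit cost`, charged to the full cohort at model entry; an
end-of-life cost of 16,306.27 per incident death, accrued in the death
cycle.  Utilities are 0.76 (rPFS) and 0.68 (PD); the rPFS utility is
reduced by the incidence-weighted AE disutilities for the whole
pre-progression duration.  An AE with no published cost or disutility
(neutropenia) contributes zero.  Half-cycle correction averages start- and
end-of-cycle occupancy; discounting, when enabled, is evaluated at cycle
midpoints, consistent with that correction.

### Calibrated baseline configuration

The source tables do not fix which alive states accrue supportive care,
nor do the published arm totals behave as if the stated 5% discount rate
had been applied.  Both choices were therefore calibrated once against the
published base-case totals by grid search over {discount costs? × discount
QALYs? × supportive care in PD only / in both alive states}:

* discounting of costs: **off** (5% discounting puts every arm's cost
  25–38% below the published totals; undiscounted costs land within 10%);
* discounting of QALYs: **off** (5% discounting puts QALYs 21–37% low;
  undiscounted QALYs land within 6% for two of three arms);
* supportive care: **both alive states** (PD-only accrual leaves costs
  7–25% below the published totals; all-alive accrual lands within 10%).

The 5% annual rate remains in the configuration (`ModelSettings`) with
separate `discount_costs` / `discount_qalys` switches, so the fully
discounted variant is one flag away.

### A structural limitation of the published inputs

With the hazard ratios applied multiplicatively as printed, apalutamide's
curves weakly dominate enzalutamide's (HR 0.76 rPFS, 0.99 OS) and
darolutamide's OS is strictly worse (HR 1.24).  Any monotone model then
yields QALY(apalutamide) ≥ QALY(enzalutamide) > QALY(darolutamide) — the
*reverse* of the published ordering, in which darolutamide attains the
highest QALYs and dominates both comparators.  The published totals are
therefore not derivable from the published inputs; this package follows
the printed inputs and formula, reproduces enzalutamide and apalutamide
within a few percent, and reports the darolutamide discrepancy (and the
ICER/threshold quantities that inherit it) rather than adjusting toward
the published numbers.  (Dividing by the hazard ratios instead — a
plausible sign error in the original implementation — reproduces the
published QALY ordering but not the cost ordering, and contradicts the
printed adjustment rule, so it is not adopted.)

## Incremental analysis

For a comparison of strategy *b* against reference *a*:
`ICER = ΔC/ΔQ` with deltas `b − a`; dominance is classified from the delta
signs, and decisions at a willingness-to-pay (WTP) threshold use net
monetary benefit `NMB = WTP × QALYs − cost` (baseline WTP: 287,391
yuan/QALY, three times 2024 per-capita GDP).  Negative ICERs are reported
numerically alongside the dominance flag, since the sign alone is
ambiguous.  The threshold-price solver bisects a chosen parameter (by
default the apalutamide per-cycle drug cost in the
enzalutamide-vs-apalutamide comparison) until the ICER equals the WTP,
to relative tolerance 1e−6.

## One-way sensitivity analysis

Each registry parameter is pushed to its lower/upper bound with the rest at
baseline.  Bounds: published 95% CIs for hazard ratios and utilities;
institutional-tier prices for imaging; every bound pair that is a rounded
±20% of baseline is regenerated exactly as 0.8×/1.2× baseline to avoid
rounding drift.  Rows are ranked by ICER span; because a span is not
interpretable across a dominance-quadrant change, the NMB-difference
endpoints and a quadrant-crossing flag are reported per row.  The ranking
metric (ICER span rather than NMB span) is a package choice; the ordering
is deterministic (span, then name) and invariant to input permutation.

## Probabilistic sensitivity analysis

Distributions are derived from baseline + bounds by method of moments with
the bounds read as a 95% interval, `sd = (high − low)/3.92`:

* **Gamma** (costs): `shape = (mean/sd)²`, `rate = mean/sd²`;
* **Beta** (utilities, probabilities): moment-matched on [0, 1];
  disutilities as Beta on the magnitude, negated on sampling; the discount
  rate as `0.08 × Beta` matched to mean 0.05 on its 0–8% support;
* **Lognormal** (hazard ratios): `log-mean = ln(baseline)` (the baseline is
  the median), `log-sd = (ln high − ln low)/3.92`.

Each of the 10,000 iterations draws one joint parameter vector (draws are
independent across parameters; no correlation structure is published),
rebuilds the comparator curves from the HR draws, and evaluates all three
arms.  CEAC winners are defined by maximum NMB with ties split equally.
A single `numpy.random.default_rng(seed)` generator draws all parameters
in sorted registry order, making the whole analysis bitwise reproducible
for a given seed (default 20251016, recorded in every run log).

## Synthetic digitized curves and IPD reconstruction

The extrapolation stage of the original workflow starts from hand-digitized
Kaplan–Meier figures, which cannot be redistributed; the `synthetic_km`
module generates equivalent artifacts from known ground truth so that the
whole digitize → reconstruct → fit path stays testable.  Event times are
drawn by inverse CDF from `S(t) = exp(−λ t^γ)`; administrative censoring
uses uniform accrual over 12 cycles with a follow-up cutoff of 120 cycles
(≈19% censoring for the reference rPFS curve — a trial-like maturity),
a 2-cycle digitization grid and 12-cycle number-at-risk rows.  Optional
zero-mean uniform jitter emulates hand-tracing error (off by default so
round-trip tolerances stay interpretable).  What the generator does *not*
emulate: correlated rPFS/OS event times within patients, digitization bias
near plot axes, and non-uniform accrual.

Reconstruction is risk-set-anchored in the style of the standard published
algorithm: within each interval between number-at-risk times (taken as
half-open `(r_j, r_{j+1}]`, since a step digitized at a risk time has
already left that risk count), an integer censor count — initialized from
the KM identity and spread evenly — is adjusted until walking the digitized
steps with integer event counts reproduces the next published risk number.
In a tail with no later risk anchor the censor count is iterated to the
fixpoint at which everyone without a digitized event is censored within the
interval (the administrative-censoring reading).  Reconstructed events are
placed at step-bracket midpoints: right-edge placement produces a
systematic upward shape bias and a ~20% downward scale bias.  Weibull
fitting is right-censored MLE (converted from the fitting backend's
`S(t) = exp(−(t/λ')^ρ)` form), with a least-squares fallback on the
complementary log-log of the KM estimate if the MLE fails; fewer than two
events flags non-convergence.

A caution on the recovery tolerance: `λ` is anchored at `t = 1` cycle, far
in the left tail of event times, so its MLE is noisy and strongly
anti-correlated with `γ` — even direct fits to perfect uncensored samples
of n = 2000 recover `λ` within 5% only about half the time.  The shipped
recovery check therefore fixes the full generating conditions and seed
(documented in the test) rather than claiming a universal n = 2000
guarantee.

## Numerical choices

* Trace recursion is vectorized over cycles (cumulative products of
  per-cycle survival ratios); state vectors sum to 1 exactly by
  construction and are verified to 1e−10 against the closed forms.
* Bisection uses `scipy.optimize.bisect` with relative tolerance 1e−6;
  the absence of a sign change over the bracket is reported with the ICERs
  at both ends.
* Degenerate inputs: zero-scale curves mean zero hazard (`S ≡ 1`);
  a negative AE-adjusted utility clamps to 0 with a warning; collapsed
  sampling bounds yield a point mass.

## Known limitations

* The darolutamide arm (and every quantity downstream of it) cannot match
  the published totals for the structural reason above.
* Supportive-care and follow-up schedules, AE disutility duration, and the
  costing of the subsequent-treatment remainder are calibration choices,
  not published facts.
* No patient-level heterogeneity, tunnel states, background mortality, or
  parameter correlation in the PSA.
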