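"""Weibull curves, HR adjustment, transition probabilities, reconstruction."""

import numpy as np
import pytest
from hypothesis import given, settings as hyp_settings, strategies as st
from scipy.optimize import brentq

from mhspc_cea import (
    DigitizedKM,
    HazardRatio,
    ReconstructedIPD,
    SimulationSpec,
    WeibullSurvival,
    adjust_by_hr,
    digitize,
    fit_weibull,
    reconstruct_ipd,
    simulate_ipd,
    transition_probability,
    weibull_survival,
)
from mhspc_cea.survival import FittingError, SurvivalInputError


class TestWeibullSurvival:
    def test_survival_is_one_at_time_zero(self):
        assert weibull_survival(WeibullSurvival(2.3, 0.04), 0.0) == 1.0

    def test_zero_scale_means_zero_hazard(self):
        curve = WeibullSurvival(shape=1.7, scale=0.0)
        assert weibull_survival(curve, 123.4) == 1.0

    def test_median_matches_root_finder_oracle(self):
        # independent oracle: solve scale * t**shape = ln 2 for the median
        curve = WeibullSurvival(shape=1.426021, scale=0.001476)
        t50 = brentq(lambda t: curve.scale * t**curve.shape - np.log(2), 1e-6, 1e4)
        assert weibull_survival(curve, t50) == pytest.approx(0.5, abs=1e-12)

    def test_negative_time_rejected_naming_argument(self):
        with pytest.raises(SurvivalInputError, match="t must be non-negative"):
            weibull_survival(WeibullSurvival(1.0, 0.01), -1.0)

    def test_invalid_parameters_rejected(self):
        with pytest.raises(SurvivalInputError):
            WeibullSurvival(shape=0.0, scale=0.01)
        with pytest.raises(SurvivalInputError):
            WeibullSurvival(shape=1.0, scale=-0.01)

    @given(
        shape=st.floats(0.3, 4.0),
        scale=st.floats(1e-5, 0.5),
        t=st.floats(0.0, 300.0),
        dt=st.floats(0.0, 50.0),
    )
    @hyp_settings(max_examples=100, derandomize=True)
    def test_survival_non_increasing(self, shape, scale, t, dt):
        curve = WeibullSurvival(shape, scale)
        assert weibull_survival(curve, t + dt) <= weibull_survival(curve, t) + 1e-15


class TestHazardRatioAdjustment:
    @pytest.mark.parametrize(
        "base_scale,hr,endpoint,expected_scale",
        [
            (0.007900, 0.76, "rPFS", 0.006004),  # apalutamide rPFS
            (0.007900, 0.85, "rPFS", 0.006715),  # darolutamide rPFS
            (0.001476, 0.99, "OS", 0.001461),    # apalutamide OS
            (0.001476, 1.24, "OS", 0.001830),    # darolutamide OS
        ],
    )
    def test_published_adjusted_scales_exact_at_six_decimals(
        self, base_scale, hr, endpoint, expected_scale
    ):
        shape = 1.131400 if endpoint == "rPFS" else 1.426021
        base = WeibullSurvival(shape=shape, scale=base_scale)
        hr_obj = HazardRatio(point=hr, ci_lower=hr, ci_upper=hr, endpoint=endpoint)
        adjusted = adjust_by_hr(base, hr_obj, endpoint=endpoint)
        assert adjusted.shape == base.shape
        assert round(adjusted.scale, 6) == expected_scale

    def test_unit_hr_returns_identical_curve(self):
        base = WeibullSurvival(1.3, 0.004)
        hr = HazardRatio(1.0, 0.5, 2.0, "OS")
        assert adjust_by_hr(base, hr) == base

    def test_endpoint_mismatch_rejected(self):
        base = WeibullSurvival(1.3, 0.004)
        hr = HazardRatio(0.9, 0.5, 2.0, "OS")
        with pytest.raises(SurvivalInputError, match="endpoint mismatch"):
            adjust_by_hr(base, hr, endpoint="rPFS")

    def test_invalid_ci_ordering_rejected(self):
        with pytest.raises(SurvivalInputError):
            HazardRatio(point=0.8, ci_lower=0.9, ci_upper=1.2, endpoint="OS")

    @given(
        scale=st.floats(1e-5, 0.1),
        h1=st.floats(0.2, 3.0),
        h2=st.floats(0.2, 3.0),
    )
    @hyp_settings(max_examples=50, derandomize=True)
    def test_adjustment_is_multiplicative_and_shape_preserving(self, scale, h1, h2):
        base = WeibullSurvival(1.1314, scale)
        hr1 = HazardRatio(h1, h1, h1, "OS")
        hr2 = HazardRatio(h2, h2, h2, "OS")
        twice = adjust_by_hr(adjust_by_hr(base, hr1), hr2)
        assert twice.shape == base.shape
        assert twice.scale == pytest.approx(base.scale * h1 * h2, rel=1e-14)


class TestTransitionProbability:
    def test_t_equal_u_reduces_to_unconditional_probability(self):
        curve = WeibullSurvival(1.1314, 0.0079)
        tp = transition_probability(curve, t=5.0, u=5.0)
        assert tp == pytest.approx(1.0 - weibull_survival(curve, 5.0), abs=1e-14)

    def test_zero_scale_gives_zero_probability(self):
        assert transition_probability(WeibullSurvival(1.5, 0.0), 10, 1) == 0.0

    def test_matches_survival_ratio_oracle(self):
        curve = WeibullSurvival(1.1314, 0.0079)
        expected = 1.0 - weibull_survival(curve, 10.0) / weibull_survival(curve, 9.0)
        assert transition_probability(curve, 10, 1) == pytest.approx(expected, abs=1e-12)

    def test_invalid_times_rejected(self):
        curve = WeibullSurvival(1.0, 0.01)
        with pytest.raises(SurvivalInputError):
            transition_probability(curve, t=1.0, u=2.0)
        with pytest.raises(SurvivalInputError):
            transition_probability(curve, t=1.0, u=0.0)

    @given(
        shape=st.floats(0.5, 3.0),
        scale=st.floats(1e-5, 0.05),
        t=st.floats(1.0, 195.0),
        u=st.floats(0.1, 1.0),
    )
    @hyp_settings(max_examples=150, derandomize=True)
    def test_formula_equivalence_with_conditional_survival(self, shape, scale, t, u):
        from hypothesis import assume

        # keep the survival-ratio oracle itself representable: for very large
        # cumulative hazard both S(t) and S(t-u) underflow to 0/0
        assume(scale * t**shape < 500.0)
        curve = WeibullSurvival(shape, scale)
        ratio = 1.0 - weibull_survival(curve, t) / weibull_survival(curve, t - u)
        assert transition_probability(curve, t, u) == pytest.approx(ratio, abs=1e-12)


class TestDigitizedKMValidation:
    def test_increasing_survival_rejected_with_index(self):
        with pytest.raises(SurvivalInputError, match="index 2"):
            DigitizedKM(
                times=[0, 1, 2, 3],
                survival=[1.0, 0.9, 0.95, 0.8],
                risk_times=[0],
                numbers_at_risk=[100],
            )

    def test_increasing_risk_set_rejected(self):
        with pytest.raises(SurvivalInputError, match="numbers at risk increase"):
            DigitizedKM(
                times=[0, 1, 2],
                survival=[1.0, 0.9, 0.8],
                risk_times=[0, 1, 2],
                numbers_at_risk=[100, 80, 90],
            )


class TestReconstruction:
    def test_round_trip_matches_digitized_curve(self):
        # KM of the reconstructed records must reproduce the digitized curve
        from lifelines import KaplanMeierFitter

        curve = WeibullSurvival(1.1314, 0.0079)
        spec = SimulationSpec(
            curve=curve, n_patients=500, censoring="none",
            reporting_grid=tuple(np.arange(0, 241, 4.0)),
            risk_report_times=tuple(np.arange(0, 241, 24.0)), seed=42,
        )
        km = digitize(simulate_ipd(spec), spec)
        rec = reconstruct_ipd(km)
        fitted = KaplanMeierFitter().fit(rec.time, rec.event)
        back = fitted.survival_function_at_times(km.times).to_numpy()
        assert np.abs(back - km.survival).max() < 0.02

    def test_flat_curve_yields_all_censored(self):
        km = DigitizedKM(
            times=[0.0, 10.0, 20.0],
            survival=[1.0, 1.0, 1.0],
            risk_times=[0.0, 10.0, 20.0],
            numbers_at_risk=[50, 50, 50],
        )
        rec = reconstruct_ipd(km)
        assert rec.n == 50
        assert rec.n_events == 0
        assert np.all(rec.time == 20.0)

    def test_record_count_equals_initial_risk_set(self):
        curve = WeibullSurvival(1.1314, 0.0079)
        spec = SimulationSpec(curve=curve, n_patients=300, censoring="uniform_admin", seed=5)
        km = digitize(simulate_ipd(spec), spec)
        rec = reconstruct_ipd(km)
        assert rec.n == km.numbers_at_risk[0]
        assert rec.n_events <= km.numbers_at_risk[0]
        assert rec.time.min() >= 0 and rec.time.max() <= km.times[-1]


class TestWeibullFit:
    def test_recovers_generating_parameters(self):
        # ~10% random censoring, fixed seed; n chosen so the scale's sampling
        # error (which the anchored-at-one-cycle parameterization amplifies)
        # sits well inside the 5% tolerance
        rng = np.random.default_rng(11)
        true = WeibullSurvival(1.1314, 0.0079)
        n = 20_000
        t_event = (-np.log(rng.random(n)) / true.scale) ** (1 / true.shape)
        censor = rng.uniform(0, 400, n)
        obs = np.minimum(t_event, censor)
        event = (t_event <= censor).astype(int)
        fit = fit_weibull(ReconstructedIPD(time=obs, event=event))
        assert fit.converged
        assert fit.curve.shape == pytest.approx(true.shape, rel=0.05)
        assert fit.curve.scale == pytest.approx(true.scale, rel=0.05)

    def test_exponential_data_shape_ci_covers_one(self):
        rng = np.random.default_rng(3)
        t = rng.exponential(scale=50.0, size=1500)
        fit = fit_weibull(ReconstructedIPD(time=t, event=np.ones(1500, dtype=int)))
        lo, hi = fit.shape_ci
        assert lo <= 1.0 <= hi

    def test_single_event_flags_non_convergence_without_crash(self):
        times = np.array([5.0] + [10.0] * 30)
        events = np.array([1] + [0] * 30)
        fit = fit_weibull(ReconstructedIPD(time=times, event=events))
        assert not fit.converged

    def test_all_censored_raises_fitting_error(self):
        with pytest.raises(FittingError, match="censored"):
            fit_weibull(ReconstructedIPD(time=np.ones(20), event=np.zeros(20, dtype=int)))
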