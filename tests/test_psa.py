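"""Sampling distributions, Monte Carlo reproducibility, CEAC behavior."""

import math

import numpy as np
import pandas as pd
import pytest

from mhspc_cea import (
    build_distribution,
    ceac,
    default_distributions,
    evaluate_all,
    run_psa,
    scatter_table,
)


class TestBuildDistribution:
    def test_gamma_mean_matches_baseline_at_large_n(self):
        spec = build_distribution("cost_enzalutamide", "gamma", 7795.2, 6236.16, 9354.24)
        draws = spec.sample(np.random.default_rng(0), 100_000)
        assert draws.mean() == pytest.approx(7795.2, rel=0.02)
        assert draws.std() == pytest.approx((9354.24 - 6236.16) / 3.92, rel=0.02)
        assert (draws > 0).all()

    def test_beta_mean_and_support(self):
        spec = build_distribution("u_rpfs", "beta", 0.76, 0.68, 0.84)
        draws = spec.sample(np.random.default_rng(1), 100_000)
        assert draws.mean() == pytest.approx(0.76, rel=0.02)
        assert ((draws > 0) & (draws < 1)).all()

    def test_negative_disutility_sampled_as_negated_beta(self):
        spec = build_distribution("disutil_fatigue", "beta", -0.115, -0.138, -0.092)
        draws = spec.sample(np.random.default_rng(2), 50_000)
        assert (draws <= 0).all()
        assert draws.mean() == pytest.approx(-0.115, rel=0.02)

    def test_discount_rate_beta_rescaled_to_its_support(self):
        spec = build_distribution("discount_rate", "beta", 0.05, 0.0, 0.08, support=0.08)
        draws = spec.sample(np.random.default_rng(3), 100_000)
        assert ((draws >= 0) & (draws <= 0.08)).all()
        assert draws.mean() == pytest.approx(0.05, rel=0.02)

    def test_lognormal_closed_form_parameters(self):
        spec = build_distribution("hr_rpfs_ave", "lognormal", 0.76, 0.26, 2.18)
        assert spec.derived_params["log_mean"] == pytest.approx(math.log(0.76), abs=1e-12)
        assert spec.derived_params["log_sd"] == pytest.approx(
            (math.log(2.18) - math.log(0.26)) / 3.92, abs=1e-9
        )
        # anchored at the median
        draws = spec.sample(np.random.default_rng(4), 100_000)
        assert np.median(draws) == pytest.approx(0.76, rel=0.02)

    def test_collapsed_bounds_give_point_mass(self):
        spec = build_distribution("cost_adt", "gamma", 905.61, 905.61, 905.61)
        assert spec.family == "degenerate"
        assert (spec.sample(np.random.default_rng(5), 100) == 905.61).all()

    def test_infeasible_beta_rejected(self):
        with pytest.raises(ValueError, match="beta"):
            build_distribution("p", "beta", 0.5, -3.0, 4.0)

    def test_all_registry_parameters_have_valid_specs(self, config):
        specs = default_distributions(config)
        assert set(specs) == set(config.parameters)
        rng = np.random.default_rng(6)
        for key, spec in specs.items():
            fam = config.parameters[key].distribution
            assert spec.family in (fam, "degenerate")
            draws = spec.sample(rng, 2_000)
            assert np.isfinite(draws).all()


class TestRunPsa:
    def test_same_seed_is_bitwise_identical(self, config):
        a = run_psa(config, n_iter=40, seed=123)
        b = run_psa(config, n_iter=40, seed=123)
        pd.testing.assert_frame_equal(a.frame, b.frame)
        c = run_psa(config, n_iter=40, seed=124)
        assert not a.frame.equals(c.frame)

    def test_degenerate_specs_reproduce_base_case(self, config):
        degenerate = {
            key: build_distribution(key, "gamma", s.baseline, s.baseline, s.baseline)
            for key, s in config.parameters.items()
        }
        result = run_psa(config, n_iter=5, seed=9, specs=degenerate)
        base = evaluate_all(config)
        for arm, out in base.items():
            sub = result.frame[result.frame.strategy == arm]
            assert np.allclose(sub["cost"], out.total_cost)
            assert np.allclose(sub["qalys"], out.total_qalys)

    def test_mean_outcomes_near_base_case_within_monte_carlo_error(self, config):
        # outcomes are linear in costs and utilities, so with the (nonlinear)
        # hazard-ratio draws pinned at baseline the Monte Carlo mean must sit
        # within sampling error of the deterministic base case
        specs = default_distributions(config)
        for key in ("hr_rpfs_ave", "hr_rpfs_dve", "hr_os_ave", "hr_os_dve"):
            s = config.parameters[key]
            specs[key] = build_distribution(key, "gamma", s.baseline, s.baseline, s.baseline)
        result = run_psa(config, n_iter=400, seed=7, specs=specs)
        base = evaluate_all(config)
        costs, qalys = result.wide()
        for arm in costs.columns:
            se_c = costs[arm].std() / np.sqrt(len(costs))
            se_q = qalys[arm].std() / np.sqrt(len(qalys))
            assert abs(costs[arm].mean() - base[arm].total_cost) < 3 * se_c
            assert abs(qalys[arm].mean() - base[arm].total_qalys) < 3 * se_q

    def test_non_positive_iteration_count_rejected(self, config):
        with pytest.raises(ValueError):
            run_psa(config, n_iter=0)


@pytest.fixture(scope="module")
def result(config):
    return run_psa(config, n_iter=500, seed=20251016)


class TestCeacAndScatter:
    def test_probabilities_partition_unity(self, result):
        table = ceac(result, [0, 100_000, 287_391, 500_000])
        sums = table.groupby("wtp")["probability"].sum()
        assert np.allclose(sums, 1.0, atol=1e-12)

    def test_degenerate_specs_make_base_winner_certain(self, config):
        degenerate = {
            key: build_distribution(key, "gamma", s.baseline, s.baseline, s.baseline)
            for key, s in config.parameters.items()
        }
        result = run_psa(config, n_iter=3, seed=1, specs=degenerate)
        table = ceac(result, [287_391])
        assert table["probability"].max() == 1.0

    def test_two_strategy_per_iteration_qaly_winner_monotone_in_wtp(self, result):
        # restricted to two arms, the probability that the iteration's
        # higher-QALY draw also has the higher NMB is non-decreasing in WTP:
        # per iteration the indicator is 1{wtp > delta_cost / delta_qalys}
        costs, qalys = result.wide()
        dq = (qalys["Enza_ADT"] - qalys["Apa_ADT"]).to_numpy()
        dc = (costs["Enza_ADT"] - costs["Apa_ADT"]).to_numpy()
        sign = np.sign(dq)
        probs = []
        for w in range(0, 1_000_001, 50_000):
            wins = sign * (w * dq - dc) > 0  # higher-QALY arm has higher NMB
            probs.append(wins.mean())
        assert np.all(np.diff(probs) >= -1e-12)

    def test_empty_grid_rejected(self, result):
        with pytest.raises(ValueError):
            ceac(result, [])

    def test_scatter_reference_block_is_zero(self, result):
        table = scatter_table(result, "Apa_ADT")
        ref = table[table.comparator == "Apa_ADT"]
        assert len(ref) == result.n_iter
        assert (ref["delta_cost"] == 0).all() and (ref["delta_qalys"] == 0).all()

    def test_scatter_row_count_per_comparator(self, result):
        table = scatter_table(result, "Enza_ADT")
        assert table.groupby("comparator").size().eq(result.n_iter).all()

    def test_scatter_means_match_deterministic_deltas_within_3se(self, config):
        specs = default_distributions(config)
        for key in ("hr_rpfs_ave", "hr_rpfs_dve", "hr_os_ave", "hr_os_dve"):
            s = config.parameters[key]
            specs[key] = build_distribution(key, "gamma", s.baseline, s.baseline, s.baseline)
        result = run_psa(config, n_iter=400, seed=77, specs=specs)
        table = scatter_table(result, "Enza_ADT")
        base = evaluate_all(config)
        sub = table[table.comparator == "Apa_ADT"]
        for col, det in (
            ("delta_cost", base["Apa_ADT"].total_cost - base["Enza_ADT"].total_cost),
            ("delta_qalys", base["Apa_ADT"].total_qalys - base["Enza_ADT"].total_qalys),
        ):
            se = sub[col].std() / np.sqrt(len(sub))
            assert abs(sub[col].mean() - det) < 3 * se + 1e-9

    def test_unknown_reference_rejected(self, result):
        with pytest.raises(KeyError):
            scatter_table(result, "Rezvilutamide")
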