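"""Randomization tests, bootstrap CIs, and survival confidence bands."""

import numpy as np
import pytest

from lansing import (
    JointModelSpec,
    MortalityParams,
    bootstrap_mean_diff,
    bootstrap_model_params,
    permutation_test,
    survival_band,
)
from lansing.simulate import sample_lifespan


class TestPermutationTest:
    def test_identical_groups_null_identity(self):
        g = [1.0, 2.0, 3.0, 4.0]
        res = permutation_test(g, g, seed=0)
        assert res.observed_diff == 0.0
        assert res.p_value == 1.0

    def test_exhaustive_enumeration_small_case(self):
        # all C(6,3) = 20 assignments; only the observed split and its mirror
        # reach |diff| = 9, so p = 2/20
        res = permutation_test([1, 2, 3], [10, 11, 12], exhaustive=True)
        assert res.exhaustive
        assert res.p_value == pytest.approx(0.1)
        assert res.observed_diff == pytest.approx(-9.0)

    def test_sampled_agrees_with_exhaustive_on_small_inputs(self):
        rng = np.random.default_rng(12)
        x1, x2 = rng.normal(0, 1, 5), rng.normal(0.8, 1, 5)
        exact = permutation_test(x1, x2, exhaustive=True)
        sampled = permutation_test(x1, x2, n_permutations=100_000, seed=1, exhaustive=False)
        assert abs(sampled.p_value - exact.p_value) < 0.02

    def test_seed_determinism(self):
        rng = np.random.default_rng(0)
        x1, x2 = rng.normal(0, 1, 40), rng.normal(0.5, 1, 40)
        r1 = permutation_test(x1, x2, n_permutations=2000, seed=5, exhaustive=False)
        r2 = permutation_test(x1, x2, n_permutations=2000, seed=5, exhaustive=False)
        assert r1 == r2

    def test_add_one_correction_floor(self):
        rng = np.random.default_rng(0)
        x1 = rng.normal(0, 0.1, 30)
        x2 = rng.normal(50, 0.1, 30)  # overwhelming separation
        res = permutation_test(x1, x2, n_permutations=999, seed=0, exhaustive=False)
        assert res.p_value >= 1 / 1000

    def test_degenerate_all_equal_warns(self):
        with pytest.warns(RuntimeWarning, match="identical"):
            res = permutation_test([2.0, 2.0, 2.0], [2.0, 2.0])
        assert res.p_value == 1.0

    def test_too_small_group_rejected(self):
        with pytest.raises(ValueError):
            permutation_test([1.0], [2.0, 3.0])


class TestBootstrapMeanDiff:
    def test_degenerate_constant_groups(self):
        ci = bootstrap_mean_diff([5.0] * 10, [2.0] * 8, n_reps=500, seed=0)
        assert ci.point == ci.lower == ci.upper == 3.0

    def test_normal_theory_width(self):
        rng = np.random.default_rng(99)
        x1 = rng.normal(10, 1, 200)
        x2 = rng.normal(7, 1, 200)
        ci = bootstrap_mean_diff(x1, x2, n_reps=4000, seed=1)
        assert ci.lower <= 3.0 <= ci.upper
        expected_width = 2 * 1.96 * np.sqrt(2 / 200)
        assert (ci.upper - ci.lower) == pytest.approx(expected_width, rel=0.25)

    def test_point_inside_interval(self):
        rng = np.random.default_rng(3)
        ci = bootstrap_mean_diff(rng.exponential(5, 80), rng.exponential(4, 90),
                                 n_reps=2000, seed=2)
        assert ci.lower <= ci.point <= ci.upper

    def test_low_rep_warning(self):
        with pytest.warns(RuntimeWarning, match="unstable"):
            bootstrap_mean_diff([1.0, 2.0], [3.0, 4.0], n_reps=50, seed=0)


class TestBootstrapModelParams:
    def test_seed_determinism(self):
        rng = np.random.default_rng(21)
        ls, _ = sample_lifespan(MortalityParams("gompertz", 0.01, 0.2), rng, 150)
        b1 = bootstrap_model_params("gompertz", ls, n_reps=2, seed=11)
        b2 = bootstrap_model_params("gompertz", ls, n_reps=2, seed=11)
        assert np.array_equal(b1.draws["group1"], b2.draws["group1"], equal_nan=True)

    def test_ci_covers_generating_rate_parameter(self):
        # a 95% interval misses ~1 run in 20, so require 4 of 5 seeds to cover
        covered = 0
        for seed in range(5):
            rng = np.random.default_rng(seed)
            ls, _ = sample_lifespan(MortalityParams("logistic", 0.001, 0.25, 1.0), rng, 1000)
            boot = bootstrap_model_params("logistic", ls, n_reps=100, seed=seed)
            ci_b = boot.ci["group1"]["b"]
            covered += ci_b.lower <= 0.25 <= ci_b.upper
            assert boot.n_failed <= 10
        assert covered >= 4

    def test_joint_bootstrap_reports_both_groups(self):
        rng = np.random.default_rng(13)
        g1, _ = sample_lifespan(MortalityParams("logistic", 0.001, 0.25, 1.0), rng, 200)
        g2, _ = sample_lifespan(MortalityParams("logistic", 0.01, 0.25, 1.0), rng, 200)
        boot = bootstrap_model_params(
            JointModelSpec.from_name("Abc"), g1, g2, n_reps=30, seed=3,
            group_labels=("first", "fifth"),
        )
        assert set(boot.draws) == {"first", "fifth"}
        # common b draws must be identical across groups, distinct a must not
        assert np.array_equal(boot.draws["first"][:, 1], boot.draws["fifth"][:, 1])
        assert not np.array_equal(boot.draws["first"][:, 0], boot.draws["fifth"][:, 0])


class TestSurvivalBand:
    def test_identical_resamples_give_zero_width_band(self):
        p = MortalityParams("logistic", 0.01, 0.2, 1.0)
        ages = np.arange(0, 30)
        lower, upper = survival_band([p] * 150, ages)
        from lansing import survival

        assert np.allclose(lower, upper)
        assert np.allclose(lower, survival(p, ages))

    def test_band_is_unit_interval_at_birth(self):
        rng = np.random.default_rng(0)
        draws = np.column_stack([
            rng.uniform(0.005, 0.02, 200),
            rng.uniform(0.1, 0.3, 200),
            rng.uniform(0.5, 2.0, 200),
        ])
        lower, upper = survival_band(draws, np.arange(0, 10))
        assert lower[0] == pytest.approx(1.0)
        assert upper[0] == pytest.approx(1.0)
        assert np.all(lower <= upper)

    def test_band_contains_central_curve(self):
        rng = np.random.default_rng(1)
        draws = np.column_stack([
            np.exp(rng.normal(np.log(0.01), 0.1, 200)),
            np.exp(rng.normal(np.log(0.2), 0.1, 200)),
            np.exp(rng.normal(np.log(1.0), 0.1, 200)),
        ])
        ages = np.arange(0, 40)
        lower, upper = survival_band(draws, ages)
        from lansing import survival

        centre = survival(MortalityParams("logistic", 0.01, 0.2, 1.0), ages)
        assert np.all(lower <= centre + 1e-12)
        assert np.all(centre <= upper + 1e-12)

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            survival_band([MortalityParams("exponential", 0.1)] * 10, np.arange(5))
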