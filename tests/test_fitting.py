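"""Single-group maximum-likelihood fitting and AICc model selection."""

import numpy as np
import pytest

from lansing import (
    MortalityParams,
    aicc,
    akaike_weights,
    fit_model,
    negative_loglik,
    selection_table,
)
from lansing.simulate import sample_lifespan


def closed_form_exponential_a(lifespans):
    """Interval-censored exponential MLE, derived analytically.

    With P(L) = e^{-aL}(1 - e^{-a}), maximizing over a gives
    a_hat = ln((1 + Lbar)/Lbar).
    """
    lbar = np.mean(lifespans)
    return np.log((1 + lbar) / lbar)


class TestNegativeLoglik:
    def test_single_geometric_term(self):
        p = MortalityParams("exponential", np.log(2))
        assert negative_loglik(p, [1]) == pytest.approx(-np.log(0.25), rel=1e-12)

    def test_density_mode_uses_hazard_times_survival(self):
        p = MortalityParams("exponential", 0.2)
        expected = -np.sum(np.log(0.2 * np.exp(-0.2 * np.array([3, 5.0]))))
        assert negative_loglik(p, [3, 5], mode="density") == pytest.approx(expected, rel=1e-12)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            negative_loglik(MortalityParams("exponential", 0.1), [])

    def test_non_integer_lifespans_rejected(self):
        with pytest.raises(ValueError, match="integer"):
            negative_loglik(MortalityParams("exponential", 0.1), [1.5])

    def test_underflow_clamped_with_warning(self):
        p = MortalityParams("exponential", 500.0)  # certain death long before day 900
        with pytest.warns(RuntimeWarning, match="clamping"):
            nll = negative_loglik(p, [900])
        assert np.isfinite(nll)


class TestExponentialMLE:
    def test_repeated_value_closed_form(self):
        fit = fit_model("exponential", np.full(20, 4))
        assert fit.params.a == pytest.approx(np.log(5 / 4), abs=1e-6)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_closed_form_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        lifespans = rng.integers(1, 60, size=rng.integers(10, 200))
        fit = fit_model("exponential", lifespans)
        assert fit.params.a == pytest.approx(closed_form_exponential_a(lifespans), abs=1e-6)


class TestAicc:
    def test_direct_arithmetic(self):
        assert aicc(0.0, 1, 10) == pytest.approx(2.5)

    def test_independent_arithmetic_check(self):
        assert aicc(-100.0, 3, 191) == pytest.approx(200 + 6 + 24 / 187, rel=1e-12)

    def test_large_n_limit_is_plain_aic(self):
        assert aicc(-50.0, 3, 10**9) == pytest.approx(106.0, abs=1e-5)

    def test_small_sample_domain_error(self):
        with pytest.raises(ValueError):
            aicc(-10.0, 3, 4)


class TestAkaikeWeights:
    def test_single_model(self):
        assert akaike_weights([123.4]) == pytest.approx([1.0])

    def test_weights_sum_to_one_and_order_inversely(self):
        rng = np.random.default_rng(0)
        v = rng.uniform(100, 200, size=6)
        w = akaike_weights(v)
        assert w.sum() == pytest.approx(1.0, abs=1e-12)
        assert np.all(np.argsort(-w) == np.argsort(v))

    def test_eight_candidate_deltas(self):
        # joint-suite delta-AICc values; best model's weight ~ 0.461
        deltas = [0.0, 2.02, 2.17, 2.74, 3.82, 5.48, 69.73, 77.95]
        w = akaike_weights(deltas)
        assert w[0] == pytest.approx(4.61e-1, rel=5e-3)

    def test_four_family_deltas(self):
        # single-group delta-AICc values; second model's weight ~ 4.49e-18
        w = akaike_weights([0.0, 79.89, 148.70, 481.86])
        assert w[1] == pytest.approx(4.49e-18, rel=5e-3)


class TestFitModel:
    def test_gompertz_parameter_recovery(self):
        # median over seeded replicates guards against single-draw noise
        err_a, err_b = [], []
        for seed in range(5):
            rng = np.random.default_rng(seed)
            lifespans, _ = sample_lifespan(MortalityParams("gompertz", 0.005, 0.15), rng, 5000)
            fit = fit_model("gompertz", lifespans)
            assert fit.converged
            err_a.append(abs(fit.params.a - 0.005) / 0.005)
            err_b.append(abs(fit.params.b - 0.15) / 0.15)
        assert np.median(err_a) < 0.10
        assert np.median(err_b) < 0.10

    def test_nesting_chain_dominance(self, logistic_lifespans):
        ll = {f: fit_model(f, logistic_lifespans).loglik
              for f in ("exponential", "gompertz", "logistic")}
        assert ll["logistic"] >= ll["gompertz"] - 1e-6
        assert ll["gompertz"] >= ll["exponential"] - 1e-6

    def test_order_invariance(self, logistic_lifespans):
        rng = np.random.default_rng(3)
        shuffled = rng.permutation(logistic_lifespans)
        f1 = fit_model("logistic", logistic_lifespans)
        f2 = fit_model("logistic", shuffled)
        assert f1.params == f2.params
        assert f1.loglik == f2.loglik

    def test_aicc_consistent_with_stored_loglik(self, logistic_lifespans):
        fit = fit_model("weibull", logistic_lifespans)
        assert fit.aicc == pytest.approx(aicc(fit.loglik, fit.k, fit.n), abs=1e-10)

    def test_too_few_lifespans_rejected(self):
        with pytest.raises(ValueError, match="at least"):
            fit_model("logistic", [3, 4, 5])


class TestSelectionTable:
    def test_equal_aicc_gives_uniform_weights(self):
        from lansing.fitting import FitResult

        fits = [
            FitResult(MortalityParams("exponential", 0.1), -50.0, 1, 100,
                      102.0, True, 8)
            for _ in range(4)
        ]
        table = selection_table(fits)
        assert np.allclose(table["weight"], 0.25)
        assert np.allclose(table["delta_AICc"], 0.0)

    def test_logistic_cohort_ranks_logistic_first(self):
        rng = np.random.default_rng(5)
        lifespans, _ = sample_lifespan(MortalityParams("logistic", 0.001, 0.25, 1.0), rng, 2000)
        fits = [fit_model(f, lifespans) for f in ("exponential", "gompertz", "weibull", "logistic")]
        table = selection_table(fits)
        assert table.iloc[0]["model"] == "logistic"
        assert table["weight"].sum() == pytest.approx(1.0, abs=1e-12)
        assert table.iloc[0]["delta_AICc"] == 0.0

    def test_mismatched_sample_sizes_rejected(self):
        f1 = fit_model("exponential", [2, 3, 4, 5])
        f2 = fit_model("exponential", [2, 3, 4, 5, 6])
        with pytest.raises(ValueError, match="different datasets"):
            selection_table([f1, f2])
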