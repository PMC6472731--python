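"""Likelihood, fitting, and cross-validation tests."""

import numpy as np
import pytest

import imbayes as ib
from imbayes.inference import LikelihoodEvaluator
from imbayes.observers import get_model


def make_observed_dataset(cond, model, params, n, seed):
    ts = ib.generate_dataset(cond, n, seed=seed)
    return ib.simulate_responses(get_model(model), ts, params, seed=seed + 1)


class TestTrialLikelihood:
    def test_full_lapse_probability_is_half(self, short_cond):
        params = ib.ParamVector(sigma_low=4, sigma_high=2, lapse=1.0)
        ts = make_observed_dataset(short_cond, "flawless_bayes", params, 20, 40)
        ev = LikelihoodEvaluator(
            get_model("flawless_bayes"), ts, ib.MCConfig(n_mc=200, seed=0)
        )
        np.testing.assert_allclose(ev.response_probabilities(params), 0.5)
        assert ev.loglik(params) == pytest.approx(20 * np.log(0.5))

    def test_closed_form_path_gives_exact_lapse_probabilities(self, unlimited_cond):
        params = ib.ParamVector(lapse=0.08)
        ts = make_observed_dataset(
            unlimited_cond, "flawless_bayes", params, 500, 41
        )
        ev = LikelihoodEvaluator(
            get_model("flawless_bayes"), ts, ib.MCConfig(n_mc=100, seed=0)
        )
        p = ev.response_probabilities(params)
        d = ib.bayes_decision_variable(
            ts.orientations, 0.0, unlimited_cond
        )
        match = (d > 0) == ts.response.astype(bool)
        expected = np.where(match, 1 - 0.08 / 2, 0.08 / 2)
        np.testing.assert_allclose(p, expected)

    def test_closed_form_loglik_is_additive(self, unlimited_cond):
        params = ib.ParamVector(lapse=0.1)
        ts = make_observed_dataset(
            unlimited_cond, "flawless_bayes", params, 400, 42
        )
        mc = ib.MCConfig(n_mc=100, seed=0)
        spec = get_model("flawless_bayes")
        full = ib.dataset_log_likelihood(spec, ts, params, mc)
        half_a = ib.dataset_log_likelihood(
            spec, ts.subset(np.arange(400) < 200), params, mc
        )
        half_b = ib.dataset_log_likelihood(
            spec, ts.subset(np.arange(400) >= 200), params, mc
        )
        assert full == pytest.approx(half_a + half_b, rel=1e-12)

    def test_common_random_numbers_are_bit_identical(self, short_cond):
        params = ib.ParamVector(sigma_low=4, sigma_high=2, lapse=0.02)
        ts = make_observed_dataset(short_cond, "flawless_bayes", params, 100, 43)
        mc = ib.MCConfig(n_mc=500, seed=5)
        spec = get_model("flawless_bayes")
        ll1 = ib.dataset_log_likelihood(spec, ts, params, mc)
        ll2 = ib.dataset_log_likelihood(spec, ts, params, mc)
        assert ll1 == ll2

    def test_mc_probability_agrees_with_high_resolution_oracle(self, short_cond):
        params = ib.ParamVector(sigma_low=4, sigma_high=2, lapse=0.02)
        ts = make_observed_dataset(short_cond, "flawless_bayes", params, 10, 44)
        spec = get_model("flawless_bayes")
        for trial in ts.trials():
            p_lo = ib.trial_response_probability(
                spec, trial, params, short_cond, ib.MCConfig(n_mc=50_000, seed=6)
            )
            p_hi = ib.trial_response_probability(
                spec, trial, params, short_cond, ib.MCConfig(n_mc=400_000, seed=7)
            )
            se = np.sqrt(max(p_hi * (1 - p_hi), 1e-4) / 50_000)
            assert abs(p_lo - p_hi) < 4 * se

    def test_generating_parameters_beat_perturbed_ones(self, short_cond):
        spec = get_model("flawless_bayes")
        params = ib.ParamVector(sigma_low=5, sigma_high=2.5, lapse=0.02)
        mc = ib.MCConfig(n_mc=400, seed=8)
        wins = 0
        n_sets = 6
        for i in range(n_sets):
            ts = make_observed_dataset(
                short_cond, "flawless_bayes", params, 800, 50 + i
            )
            ll_true = ib.dataset_log_likelihood(spec, ts, params, mc)
            ll_pert = ib.dataset_log_likelihood(
                spec,
                ts,
                params.updated(sigma_low=7.5, sigma_high=1.25),
                mc,
            )
            wins += ll_true >= ll_pert
        assert wins >= n_sets - 1

    def test_missing_response_rejected(self, short_cond):
        ts = ib.generate_dataset(short_cond, 10, seed=60)
        with pytest.raises(ValueError):
            LikelihoodEvaluator(
                get_model("flawless_bayes"), ts, ib.MCConfig(n_mc=100, seed=0)
            )


class TestFitting:
    def test_aic_identity(self, unlimited_cond):
        params = ib.ParamVector(lapse=0.05, mu_late=0.2, sigma_late=0.8)
        ts = make_observed_dataset(
            unlimited_cond, "imperfect_bayes", params, 400, 61
        )
        fit = ib.fit_model(
            get_model("imperfect_bayes"), ts,
            mc=ib.MCConfig(n_mc=100, seed=0),
            opt=ib.OptConfig(n_starts=3, seed=1),
        )
        assert fit.aic == pytest.approx(2 * fit.k_params - 2 * fit.loglik)
        assert fit.k_params == 3  # lapse, mu_late, sigma_late (unlimited)

    def test_parameter_count_matches_model_table(self):
        expect_short = {
            "flawless_bayes": 3, "imperfect_bayes": 5, "ignorant_bayes": 4,
            "imperfect_ignorant_bayes": 6, "max": 4, "min_dev": 4,
            "minkowski": 5, "mean": 4, "variance": 4, "imperfect_max": 5,
            "imperfect_min_dev": 5, "imperfect_minkowski": 6,
            "imperfect_mean": 5, "imperfect_variance": 5,
            "sampling_bayes": 4,
        }
        for name, k in expect_short.items():
            assert get_model(name).k_params("short") == k, name

    def test_fit_recovers_late_noise_parameters_closed_form(self, unlimited_cond):
        # in the closed-form regime the imperfect Bayesian's parameters are
        # cheap to fit and should land near the generating values
        params = ib.ParamVector(lapse=0.02, mu_late=0.5, sigma_late=1.0)
        ts = make_observed_dataset(
            unlimited_cond, "imperfect_bayes", params, 2000, 62
        )
        fit = ib.fit_model(
            get_model("imperfect_bayes"), ts,
            mc=ib.MCConfig(n_mc=100, seed=0),
            opt=ib.OptConfig(n_starts=5, seed=2),
        )
        assert fit.params_hat.mu_late == pytest.approx(0.5, abs=0.3)
        assert fit.params_hat.sigma_late == pytest.approx(1.0, rel=0.35)

    def test_fitted_loglik_at_least_truth(self, short_cond):
        spec = get_model("flawless_bayes")
        params = ib.ParamVector(sigma_low=5, sigma_high=2.5, lapse=0.02)
        ts = make_observed_dataset(short_cond, "flawless_bayes", params, 500, 63)
        mc = ib.MCConfig(n_mc=300, seed=9)
        fit = ib.fit_model(
            spec, ts, priors=ib.PriorSpec(5.0, 2.5), mc=mc,
            opt=ib.OptConfig(n_starts=2, seed=3, max_fevals=200),
        )
        ll_true = ib.dataset_log_likelihood(spec, ts, params, mc)
        # MAP point should not be much worse than the generating parameters
        assert fit.loglik > ll_true - 5.0

    def test_own_model_beats_foreign_model(self, unlimited_cond):
        params = ib.ParamVector(lapse=0.02, mu_late=0.0, sigma_late=0.8)
        mc = ib.MCConfig(n_mc=100, seed=0)
        better = 0
        for i in range(4):
            ts = make_observed_dataset(
                unlimited_cond, "imperfect_bayes", params, 500, 70 + i
            )
            f_own = ib.fit_model(
                get_model("imperfect_bayes"), ts, mc=mc,
                opt=ib.OptConfig(n_starts=3, seed=i),
            )
            f_for = ib.fit_model(
                get_model("variance"), ts, mc=mc,
                opt=ib.OptConfig(n_starts=3, seed=i),
            )
            better += f_own.loglik >= f_for.loglik
        assert better >= 3

    def test_unconstrained_lapse_exceeds_constrained(self, unlimited_cond):
        # decision noise plus real lapses: without the lapse prior the
        # flawless model explains decision noise away as guessing
        params = ib.ParamVector(lapse=0.05, mu_late=0.0, sigma_late=1.5)
        ts = make_observed_dataset(
            unlimited_cond, "imperfect_bayes", params, 2000, 80
        )
        spec = get_model("flawless_bayes")
        mc = ib.MCConfig(n_mc=100, seed=0)
        f_unc = ib.fit_model(
            spec, ts, priors=None, mc=mc, opt=ib.OptConfig(n_starts=4, seed=4)
        )
        f_con = ib.fit_model(
            spec, ts, priors=ib.PriorSpec(4.0, 2.0), mc=mc,
            opt=ib.OptConfig(n_starts=4, seed=4),
        )
        assert f_unc.params_hat.lapse >= f_con.params_hat.lapse


class TestCrossValidation:
    def test_fold_sizes_partition_the_data(self, unlimited_cond, rng):
        n = 1500
        perm = np.random.default_rng(0).permutation(n)
        folds = np.array_split(perm, 5)
        assert [len(f) for f in folds] == [300] * 5
        assert sorted(np.concatenate(folds)) == list(range(n))

    def test_cvll_below_training_loglik(self, unlimited_cond):
        params = ib.ParamVector(lapse=0.05, mu_late=0.2, sigma_late=1.0)
        mc = ib.MCConfig(n_mc=100, seed=0)
        spec = get_model("imperfect_bayes")
        gaps = []
        for i in range(3):
            ts = make_observed_dataset(
                unlimited_cond, "imperfect_bayes", params, 400, 90 + i
            )
            fit = ib.fit_model(
                spec, ts, mc=mc, opt=ib.OptConfig(n_starts=3, seed=i)
            )
            cvll = ib.cross_validated_loglik(
                spec, ts, k=5, mc=mc,
                opt=ib.OptConfig(n_starts=2, seed=i), seed=i,
            )
            gaps.append(fit.loglik - cvll)
        assert np.mean(gaps) > 0

    def test_guessing_model_cvll(self, unlimited_cond):
        params = ib.ParamVector(lapse=1.0)
        ts = make_observed_dataset(
            unlimited_cond, "flawless_bayes", params, 200, 95
        )
        mc = ib.MCConfig(n_mc=100, seed=0)
        # held-out loglik at lapse = 1 is n log(1/2) regardless of the fit
        ll = ib.dataset_log_likelihood(
            get_model("flawless_bayes"), ts, params, mc
        )
        assert ll == pytest.approx(200 * np.log(0.5))

    def test_bad_fold_counts_rejected(self, unlimited_cond):
        params = ib.ParamVector(lapse=0.1)
        ts = make_observed_dataset(
            unlimited_cond, "flawless_bayes", params, 30, 96
        )
        with pytest.raises(ValueError):
            ib.cross_validated_loglik(get_model("flawless_bayes"), ts, k=1)
        with pytest.raises(ValueError):
            ib.cross_validated_loglik(get_model("flawless_bayes"), ts, k=31)
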