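"""Decision-variable and response-probability tests, including the
quadrature oracle for the optimal observer."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.integrate import quad
from scipy.stats import norm

import imbayes as ib
from imbayes.observers import (
    core_present_probability,
    decision_variable,
    get_model,
    local_evidence,
)


def quadrature_log_posterior_ratio(x, sigma, condition):
    """Independent oracle: log p(T=1|x)/p(T=0|x) by numerical
    marginalization of the generative model over the stimulus values,
    evaluated in log space to survive deep-tail observations."""
    from scipy.special import logsumexp

    mu, sig_ext = condition.mu_target, condition.sigma_external

    def log_like(xi, si, mean):
        # log integral of N(xi; s, si) N(s; mean, sig_ext) ds
        width = 10 * (si + sig_ext)
        lo = min(xi, mean) - width
        hi = max(xi, mean) + width
        grid = np.linspace(lo, hi, 201)
        logf = lambda s: norm.logpdf(xi, s, si) + norm.logpdf(s, mean, sig_ext)
        shift = logf(grid).max()
        val, _ = quad(
            lambda s: np.exp(logf(s) - shift), lo, hi,
            epsabs=1e-300, epsrel=1e-12, limit=200,
        )
        return shift + np.log(val)

    ll_dist = np.array([log_like(xi, si, -mu) for xi, si in zip(x, sigma)])
    ll_targ = np.array([log_like(xi, si, +mu) for xi, si in zip(x, sigma)])
    log_p_absent = ll_dist.sum()
    log_p_present = logsumexp(
        [ll_targ[L] - ll_dist[L] + log_p_absent for L in range(len(x))]
    ) - np.log(len(x))
    return log_p_present - log_p_absent


class TestLocalEvidence:
    def test_zero_observation_gives_equal_evidence(self, short_cond):
        assert local_evidence(0.0, 2.0, short_cond) == pytest.approx(1.0)

    def test_hand_value(self):
        cond = ib.Condition("short", mu_target=5.0, sigma_external=0.0)
        # exp((10^2 - 0)/50) = e^2
        assert local_evidence(5.0, 5.0, cond) == pytest.approx(np.e**2)

    @given(
        x=st.floats(-15, 15),
        sigma=st.floats(0.7, 20),
        sig_ext=st.floats(0.0, 10),
    )
    @settings(max_examples=100, deadline=None)
    def test_quadratic_form_equals_exponential_form(self, x, sigma, sig_ext):
        cond = ib.Condition("short", mu_target=5.0, sigma_external=sig_ext)
        expected = np.exp(2 * 5.0 * x / (sigma**2 + sig_ext**2))
        assert local_evidence(x, sigma, cond) == pytest.approx(
            expected, rel=1e-12
        )

    def test_strictly_increasing_in_observation(self, short_cond):
        xs = np.linspace(-20, 20, 101)
        vals = local_evidence(xs, 3.0, short_cond)
        assert np.all(np.diff(vals) > 0)

    def test_degenerate_noise_rejected(self):
        cond = ib.Condition("short", mu_target=5.0, sigma_external=0.0)
        with pytest.raises(Exception):
            local_evidence(1.0, 0.0, cond)


class TestDecisionVariables:
    def test_flawless_bayes_zero_observations(self, short_cond):
        spec = get_model("flawless_bayes")
        params = ib.ParamVector(sigma_low=4, sigma_high=2)
        d = decision_variable(
            spec, np.zeros(4), np.array([True, False, True, False]), params,
            short_cond,
        )
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_max_model_definition(self, short_cond):
        spec = get_model("max")
        d = decision_variable(
            spec,
            np.array([1.0, -3.0, 2.0, 0.0]),
            np.zeros(4, bool),
            ib.ParamVector(criterion=0.0),
            short_cond,
        )
        assert d == 2.0

    def test_variance_model_uses_population_convention(self, short_cond):
        spec = get_model("variance")
        x = np.array([2.0, -2.0, 2.0, -2.0])
        d = decision_variable(
            spec, x, np.zeros(4, bool), ib.ParamVector(criterion=0.0),
            short_cond,
        )
        # independent moment route: E[x^2] - mean^2
        assert d == pytest.approx(np.mean(x**2) - np.mean(x) ** 2)
        assert d == pytest.approx(4.0)

    @pytest.mark.parametrize(
        "model", ["flawless_bayes", "max", "min_dev", "minkowski", "mean", "variance"]
    )
    def test_permutation_invariance(self, model, short_cond, rng):
        spec = get_model(model)
        params = ib.ParamVector(
            sigma_low=4, sigma_high=2, criterion=0.0, beta=1.7
        )
        x = rng.normal(0, 5, 4)
        rel = np.array([True, False, False, True])
        perm = rng.permutation(4)
        d1 = decision_variable(spec, x, rel, params, short_cond)
        d2 = decision_variable(spec, x[perm], rel[perm], params, short_cond)
        assert d1 == pytest.approx(d2, rel=1e-12)

    def test_matches_quadrature_oracle(self, rng):
        cond = ib.Condition("short", mu_target=4.0, sigma_external=2.5)
        spec = get_model("flawless_bayes")
        for _ in range(20):
            sl, sh = rng.uniform(1, 8, 2)
            params = ib.ParamVector(sigma_low=sl, sigma_high=sh)
            rel = rng.random(4) < 0.5
            x = rng.normal(0, 6, 4)
            d = decision_variable(spec, x, rel, params, cond)
            oracle = quadrature_log_posterior_ratio(
                x, np.where(rel, sh, sl), cond
            )
            assert d == pytest.approx(oracle, rel=1e-6, abs=1e-8)

    def test_ignorant_equals_flawless_at_equal_sigmas(self, short_cond, rng):
        x = rng.normal(0, 5, (50, 4))
        rel = rng.random((50, 4)) < 0.5
        p_fl = ib.ParamVector(sigma_low=3.0, sigma_high=3.0)
        p_ig = ib.ParamVector(sigma_low=3.0, sigma_high=3.0, sigma_single=3.0)
        d1 = decision_variable(get_model("flawless_bayes"), x, rel, p_fl, short_cond)
        d3 = decision_variable(get_model("ignorant_bayes"), x, rel, p_ig, short_cond)
        np.testing.assert_allclose(d1, d3, rtol=1e-12)

    def test_overflow_safe_for_extreme_observations(self, short_cond):
        d = decision_variable(
            get_model("flawless_bayes"),
            np.array([500.0, -500.0, 0.0, 0.0]),
            np.zeros(4, bool),
            ib.ParamVector(sigma_low=1.0, sigma_high=1.0),
            short_cond,
        )
        assert np.isfinite(d)


class TestResponseProbability:
    def test_symmetric_imperfect_bayes_is_half(self):
        spec = get_model("imperfect_bayes")
        p = core_present_probability(
            spec, np.array([0.0]), ib.ParamVector(mu_late=0.0, sigma_late=1.0)
        )
        assert p[0] == pytest.approx(0.5)

    def test_sampling_symmetry_and_binomial_value(self):
        spec = get_model("sampling_bayes")
        for n in (1, 3, 11):
            p = core_present_probability(
                spec, np.array([0.0]), ib.ParamVector(n_samples=n)
            )
            assert p[0] == pytest.approx(0.5)
        d0 = np.log(0.8 / 0.2)  # p1 = 0.8
        p = core_present_probability(
            spec, np.array([d0]), ib.ParamVector(n_samples=3)
        )
        assert p[0] == pytest.approx(0.896)  # exact binomial P(X >= 2)

    def test_even_sample_count_ties_split_fairly(self):
        spec = get_model("sampling_bayes")
        p = core_present_probability(
            spec, np.array([0.0]), ib.ParamVector(n_samples=2)
        )
        # p1 = 0.5: P(2 wins) = .25, tie .5 -> fair coin adds .25
        assert p[0] == pytest.approx(0.5)

    def test_lapse_mixing(self, short_cond):
        spec = get_model("flawless_bayes")
        x = np.array([10.0, 10.0, 10.0, 10.0])  # strong evidence, d0 > 0
        p = ib.response_probability_given_observations(
            spec, x, np.zeros(4, bool),
            ib.ParamVector(sigma_low=3, sigma_high=3, lapse=0.1),
            short_cond,
        )
        assert p == pytest.approx(0.95)

    def test_deviation_models_respond_present_below_criterion(self, short_cond):
        # an observation exactly at the expected target value is the
        # strongest possible evidence for these models
        x = np.array([short_cond.mu_target, -9.0, -9.0, -9.0])
        for model in ("min_dev", "minkowski"):
            p = ib.response_probability_given_observations(
                get_model(model), x, np.zeros(4, bool),
                ib.ParamVector(criterion=1.0, beta=2.0, lapse=0.0),
                short_cond,
            )
            if model == "min_dev":
                assert p == 1.0  # deviation 0 < c = 1

    def test_tie_with_threshold_responds_absent(self, short_cond):
        p = ib.response_probability_given_observations(
            get_model("max"),
            np.array([1.0, 0.0, 0.0, 0.0]),
            np.zeros(4, bool),
            ib.ParamVector(criterion=1.0, lapse=0.0),
            short_cond,
        )
        assert p == 0.0

    def test_zero_late_noise_warns_and_falls_back(self, short_cond):
        with pytest.warns(RuntimeWarning):
            p = core_present_probability(
                get_model("imperfect_max"),
                np.array([2.0]),
                ib.ParamVector(criterion=1.0, sigma_late=0.0),
            )
        assert p[0] == 1.0


class TestLimitEquivalences:
    def test_sampling_converges_to_flawless(self, short_cond, rng):
        x = rng.normal(0, 5, (200, 4))
        rel = rng.random((200, 4)) < 0.5
        params_fl = ib.ParamVector(sigma_low=4, sigma_high=2)
        params_sm = params_fl.updated(n_samples=1001)
        p_fl = ib.response_probability_given_observations(
            get_model("flawless_bayes"), x, rel, params_fl, short_cond
        )
        p_sm = ib.response_probability_given_observations(
            get_model("sampling_bayes"), x, rel, params_sm, short_cond
        )
        # pointwise convergence except in a shrinking band around d = 0
        d0 = decision_variable(
            get_model("flawless_bayes"), x, rel, params_fl, short_cond
        )
        away = np.abs(d0) > 0.3
        assert away.sum() > 100
        assert np.max(np.abs(p_fl - p_sm)[away]) < 0.01

    def test_vanishing_late_noise_recovers_flawless(self, short_cond, rng):
        x = rng.normal(0, 5, (200, 4))
        rel = rng.random((200, 4)) < 0.5
        base = ib.ParamVector(sigma_low=4, sigma_high=2)
        p_fl = ib.response_probability_given_observations(
            get_model("flawless_bayes"), x, rel, base, short_cond
        )
        p_im = ib.response_probability_given_observations(
            get_model("imperfect_bayes"), x, rel,
            base.updated(mu_late=0.0, sigma_late=1e-9), short_cond,
        )
        np.testing.assert_allclose(p_fl, p_im, atol=1e-9)


class TestSimulateResponses:
    def test_full_lapse_is_pure_guessing(self, short_cond):
        ts = ib.generate_dataset(short_cond, 100_000, seed=30)
        sim = ib.simulate_responses(
            get_model("flawless_bayes"), ts,
            ib.ParamVector(sigma_low=4, sigma_high=2, lapse=1.0), seed=31,
        )
        rate = sim.response.mean()
        assert abs(rate - 0.5) < 3 * 0.5 / np.sqrt(len(ts))
        # responses independent of the truth
        hr = sim.response[sim.target_present].mean()
        far = sim.response[~sim.target_present].mean()
        assert abs(hr - far) < 0.02

    def test_unlimited_zero_noise_is_deterministic(self, unlimited_cond):
        ts = ib.generate_dataset(unlimited_cond, 2000, seed=32)
        params = ib.ParamVector(lapse=0.0)
        sim = ib.simulate_responses(get_model("flawless_bayes"), ts, params, seed=33)
        d = ib.bayes_decision_variable(ts.orientations, 0.0, unlimited_cond)
        np.testing.assert_array_equal(sim.response.astype(bool), d > 0)

    def test_sampler_consistent_with_probability_function(self, short_cond):
        # replicate one trial many times; empirical response rate must match
        # the marginal response probability
        base = ib.generate_dataset(short_cond, 1, seed=34)
        n = 100_000
        ts = ib.TrialSet(
            condition=short_cond,
            orientations=np.repeat(base.orientations, n, axis=0),
            reliability_high=np.repeat(base.reliability_high, n, axis=0),
            target_present=np.repeat(base.target_present, n),
            target_location=np.repeat(base.target_location, n),
        )
        params = ib.ParamVector(
            sigma_low=4, sigma_high=2, lapse=0.05, mu_late=0.3, sigma_late=0.8
        )
        sim = ib.simulate_responses(get_model("imperfect_bayes"), ts, params, seed=35)
        rate = sim.response.mean()
        trial = next(base.trials())
        trial.response = True
        p = ib.trial_response_probability(
            get_model("imperfect_bayes"), trial, params, short_cond,
            ib.MCConfig(n_mc=100_000, seed=36),
        )
        se = np.sqrt(p * (1 - p) / n)
        assert abs(rate - p) < 4 * se
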