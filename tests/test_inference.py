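"""Sampler correctness, determinism, and posterior summaries."""

import warnings
from dataclasses import replace

import numpy as np
import pytest

from prsme import (
    LatentSimConfig,
    McmcSettings,
    MeasurementModel,
    PosteriorSamples,
    PriorSpec,
    RegressionData,
    fit_bayes,
    simulate_latent,
    summarize,
)

FAST = McmcSettings(n_chains=2, n_iter=800, n_warmup=400, seed=42)


def _samples(gamma, alpha=None):
    if alpha is None:
        alpha = np.empty(gamma.shape + (0,))
    return PosteriorSamples(gamma_draws=gamma, alpha_draws=alpha)


class TestSummarize:
    def test_constant_chain_degenerates_with_warning(self):
        draws = np.full((2, 200), 1.7)
        with pytest.warns(UserWarning, match="identical"):
            fs = summarize(_samples(draws))
        assert fs.estimate == pytest.approx(1.7, abs=1e-12)
        assert fs.ci_low == fs.ci_high == 1.7

    def test_standard_normal_quantile_oracle(self):
        rng = np.random.default_rng(123)
        draws = rng.standard_normal((4, 2000))
        fs = summarize(_samples(draws))
        assert abs(fs.estimate) < 0.04
        assert fs.ci_low == pytest.approx(-1.96, abs=0.08)
        assert fs.ci_high == pytest.approx(1.96, abs=0.08)

    def test_non_mixing_chains_warn(self):
        rng = np.random.default_rng(0)
        draws = np.stack([rng.normal(0, 0.01, 500), rng.normal(5, 0.01, 500)])
        with pytest.warns(UserWarning, match="R-hat"):
            fs = summarize(_samples(draws))
        assert fs.rhat > 1.01

    def test_too_few_draws_rejected(self):
        with pytest.raises(ValueError, match="100"):
            summarize(_samples(np.zeros((2, 20))))


class TestSettings:
    def test_invariants(self):
        with pytest.raises(ValueError, match="n_iter"):
            McmcSettings(n_iter=100, n_warmup=100)
        with pytest.raises(ValueError, match="n_chains"):
            McmcSettings(n_chains=1)
        with pytest.raises(ValueError, match="algorithm"):
            McmcSettings(algorithm="hmc")
        with pytest.raises(ValueError, match="does not match"):
            data = RegressionData([0.0] * 4, None, [0.0, 0.1, 0.2, 0.3], "linear")
            fit_bayes(data, MeasurementModel(1, 1, 5),
                      settings=replace(FAST, algorithm="mh_logistic"))


class TestFitBayes:
    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_seed_determinism(self, family):
        sim = simulate_latent(
            LatentSimConfig(n_test=80, n_validation=50, gamma_true=0.3,
                            family=family, seed=9)
        )
        me = MeasurementModel(1.0, 1.0, 50)
        a = fit_bayes(sim.test, me, settings=FAST)
        b = fit_bayes(sim.test, me, settings=FAST)
        assert np.array_equal(a.gamma_draws, b.gamma_draws)
        if family == "linear":
            assert np.array_equal(a.sigma_draws, b.sigma_draws)

    def test_no_noise_limit_matches_plain_regression(self):
        """With tau^2 at the floor the corrected fit collapses onto ordinary
        regression of Y on the (noiseless) PRS."""
        sim = simulate_latent(
            LatentSimConfig(n_test=500, n_validation=100, gamma_true=0.3,
                            slope_a=1.0, resid_var_tau2=0.0, seed=21)
        )
        with pytest.warns(UserWarning, match="floor"):
            me = MeasurementModel(1.0, 0.0, 100).floored(float(np.var(sim.test.noisy_z)))
        fs = summarize(fit_bayes(sim.test, me, settings=replace(FAST, n_iter=1500, n_warmup=500)))
        z = sim.test.noisy_z
        ols = float(z @ sim.test.outcome_y / (z @ z))
        post_sd = (fs.ci_high - fs.ci_low) / (2 * 1.96)
        assert abs(fs.estimate - ols) < 3 * post_sd

    def test_pg_and_mh_logistic_agree(self):
        """The Polya-Gamma and Metropolis samplers target the same
        posterior; their gamma means agree on a small instance."""
        data = RegressionData([1, 0, 1, 0, 1, 1], None,
                              [0.5, -0.3, 1.0, -0.8, 0.2, 1.4], "logistic")
        me = MeasurementModel(1.0, 0.5, 100)
        priors = PriorSpec(coef_scale=1.5)
        long = McmcSettings(n_chains=2, n_iter=6000, n_warmup=1000, seed=3)
        mh = summarize(fit_bayes(data, me, priors, replace(long, algorithm="mh_logistic")))
        pg = summarize(fit_bayes(data, me, priors, replace(long, algorithm="pg_logistic")))
        assert mh.estimate == pytest.approx(pg.estimate, abs=0.08)

    def test_posterior_contraction_with_n(self):
        """Posterior SD of gamma shrinks roughly as n^(-1/2)."""
        sds = {}
        for n in (500, 5000):
            sim = simulate_latent(
                LatentSimConfig(n_test=n, n_validation=2000, gamma_true=0.3, seed=4)
            )
            me = MeasurementModel(1.0, 1.0, 2000)
            fs = summarize(fit_bayes(sim.test, me, settings=FAST))
            sds[n] = (fs.ci_high - fs.ci_low) / (2 * 1.96)
        assert sds[5000] < 0.5 * sds[500]

    def test_interval_calibration_over_replicates(self):
        """On model-simulated data the 95% credible interval covers the
        truth at close to nominal rate."""
        gamma, covered, reps = 0.3, 0, 200
        me_true = MeasurementModel(1.0, 1.0, 2000)
        for r in range(reps):
            sim = simulate_latent(
                LatentSimConfig(n_test=300, n_validation=500, gamma_true=gamma,
                                seed=10_000 + r)
            )
            fs = summarize(
                fit_bayes(sim.test, me_true,
                          settings=replace(FAST, n_iter=700, n_warmup=300, seed=r))
            )
            covered += fs.ci_low <= gamma <= fs.ci_high
        assert 0.95 - 0.04 <= covered / reps <= 0.95 + 0.04
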