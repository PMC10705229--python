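"""Joint-density and link-function behaviour of the model definition."""

import numpy as np
import pytest
from scipy import stats

from prsme import (
    MeasurementModel,
    ParameterState,
    PriorSpec,
    RegressionData,
    log_joint,
    logistic_link,
)
from oracles import term_by_term_log_joint


def make_state(z, gamma=0.0, sigma=1.0, alpha=(), intercept=0.0):
    return ParameterState(
        alpha=np.asarray(alpha, float), gamma=gamma, latent_z=np.asarray(z, float),
        sigma=sigma, intercept=intercept,
    )


class TestLogJoint:
    def test_all_zero_case_closed_form(self):
        """Single observation at the origin: every Gaussian term is the
        standard-normal density at 0, plus the prior terms."""
        data = RegressionData([0.0], None, [0.0], "linear")
        me = MeasurementModel(1.0, 1.0, 10)
        priors = PriorSpec(coef_scale=10.0, sigma_scale=5.0)
        got = log_joint(make_state([0.0]), data, me, priors)
        expected = (
            3 * stats.norm.logpdf(0.0)
            + stats.norm.logpdf(0.0, scale=10.0)
            + stats.halfcauchy.logpdf(1.0, scale=5.0)
        )
        assert got == pytest.approx(expected, abs=1e-12)

    @pytest.mark.parametrize("family", ["linear", "logistic"])
    def test_matches_term_by_term_oracle(self, family):
        """Fixed 3-observation instance against an independent density sum."""
        y = [0.4, -1.1, 0.7] if family == "linear" else [1.0, 0.0, 1.0]
        w = [[0.5], [-0.2], [1.3]]
        zp = [0.9, -0.4, 0.1]
        z = [0.6, -0.8, 0.3]
        data = RegressionData(y, w, zp, family)
        me = MeasurementModel(0.8, 0.7, 25)
        priors = PriorSpec(coef_scale=3.0, sigma_scale=2.0)
        state = make_state(z, gamma=0.45, sigma=1.2, alpha=[0.25], intercept=-0.3)
        got = log_joint(state, data, me, priors)
        want = term_by_term_log_joint(
            y, w, zp, z, [0.25], 0.45, 1.2, -0.3, 0.8, 0.7, 3.0, 2.0, family
        )
        assert got == pytest.approx(want, abs=1e-10)

    def test_tau2_change_and_latent_optimum(self):
        """Doubling tau2 shifts the density when the latent covariate is not
        at Z_p/a; with gamma=0 the measurement kernel (prior removed) is
        maximized at latent = Z_p."""
        data = RegressionData([0.2], None, [1.5], "linear")
        priors = PriorSpec()
        st = make_state([0.4])
        v1 = log_joint(st, data, MeasurementModel(1.0, 0.5, 10), priors)
        v2 = log_joint(st, data, MeasurementModel(1.0, 1.0, 10), priors)
        assert v1 != v2

        me = MeasurementModel(1.0, 1e-4, 10)

        def kernel(z):
            # remove the N(0,1) latent prior so only the measurement term varies
            return log_joint(make_state([z]), data, me, priors) - stats.norm.logpdf(z)

        at_zp = kernel(1.5)
        assert all(at_zp > kernel(z) for z in (1.4, 1.45, 1.55, 1.6))

    def test_observation_order_invariance(self):
        rng = np.random.default_rng(3)
        n = 12
        y, zp, z = rng.standard_normal((3, n))
        w = rng.standard_normal((n, 2))
        alpha = [0.3, -0.2]
        perm = rng.permutation(n)
        me = MeasurementModel(0.9, 0.8, 50)
        priors = PriorSpec()
        a = log_joint(
            make_state(z, 0.2, 1.1, alpha), RegressionData(y, w, zp, "linear"), me, priors
        )
        b = log_joint(
            make_state(z[perm], 0.2, 1.1, alpha),
            RegressionData(y[perm], w[perm], zp[perm], "linear"),
            me,
            priors,
        )
        assert a == pytest.approx(b, rel=1e-12)

    def test_gamma_difference_is_closed_form_quadratic(self):
        """For the linear family the log-density difference between two
        gamma values is an explicit quadratic in the residuals."""
        rng = np.random.default_rng(7)
        n = 6
        y, zp, z = rng.standard_normal((3, n))
        data = RegressionData(y, None, zp, "linear")
        me = MeasurementModel(1.0, 1.0, 10)
        priors = PriorSpec(coef_scale=2.5)
        g1, g2, sigma = 0.2, -0.7, 1.3
        d = log_joint(make_state(z, g2, sigma), data, me, priors) - log_joint(
            make_state(z, g1, sigma), data, me, priors
        )
        want = (
            -np.sum((y - z * g2) ** 2 - (y - z * g1) ** 2) / (2 * sigma**2)
            - (g2**2 - g1**2) / (2 * priors.coef_scale**2)
        )
        assert d == pytest.approx(want, rel=1e-10)

    def test_dimension_and_coding_errors(self):
        data = RegressionData([0.0, 1.0], None, [0.1, 0.2], "linear")
        me = MeasurementModel(1.0, 1.0, 10)
        with pytest.raises(ValueError, match="latent_z"):
            log_joint(make_state([0.0]), data, me, PriorSpec())
        with pytest.raises(ValueError, match="alpha"):
            log_joint(make_state([0.0, 0.1], alpha=[1.0]), data, me, PriorSpec())
        with pytest.raises(ValueError, match="0/1"):
            RegressionData([0.0, 2.0], None, [0.1, 0.2], "logistic")

    def test_requires_floored_variance(self):
        data = RegressionData([0.0], None, [0.0], "linear")
        me = MeasurementModel(1.0, 0.0, 10)
        with pytest.raises(ValueError, match="floor"):
            log_joint(make_state([0.0]), data, me, PriorSpec())
        with pytest.warns(UserWarning, match="floor"):
            floored = me.floored(1.0)
        assert floored.resid_var_tau2 > 0


class TestLogisticLink:
    def test_midpoint_and_known_value(self):
        assert logistic_link(0.0) == 0.5
        assert logistic_link(np.log(3.0)) == pytest.approx(0.75, abs=1e-12)

    @pytest.mark.parametrize("x", [0.1, 1.0, 10.0, 700.0])
    def test_symmetry(self, x):
        assert logistic_link(x) + logistic_link(-x) == pytest.approx(1.0, abs=1e-12)

    def test_monotone_and_saturating(self):
        xs = np.linspace(-800, 800, 101)
        ps = logistic_link(xs)
        assert np.all(np.diff(ps) >= 0)
        assert np.all((ps >= 0) & (ps <= 1))
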