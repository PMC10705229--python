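"""Independent oracles used by the test suite.

Each oracle re-derives a quantity by a route deliberately different from
the package implementation: explicit per-term density sums, dense-grid
integration with the latent covariate marginalized analytically, and
importance sampling.  They were written against the model definition
before the samplers and must stay free of any prsme internals.
"""

import numpy as np
from scipy import stats


def term_by_term_log_joint(
    y, w, zp, z, alpha, gamma, sigma, intercept, a, tau2, coef_scale, sigma_scale, family
):
    """Plain per-observation, per-term density sum of the unnormalized log
    posterior: measurement density + latent prior + outcome likelihood +
    coefficient priors (+ sigma / intercept terms by family)."""
    y, zp, z = map(np.atleast_1d, (y, zp, z))
    alpha = np.atleast_1d(alpha)
    w = np.atleast_2d(w) if np.size(w) else np.empty((len(y), 0))
    total = 0.0
    for i in range(len(y)):
        total += stats.norm.logpdf(zp[i], loc=a * z[i], scale=np.sqrt(tau2))
        total += stats.norm.logpdf(z[i], loc=0.0, scale=1.0)
        eta = float(w[i] @ alpha) + z[i] * gamma
        if family == "linear":
            total += stats.norm.logpdf(y[i], loc=eta, scale=sigma)
        else:
            p = 1.0 / (1.0 + np.exp(-(eta + intercept)))
            total += stats.bernoulli.logpmf(int(y[i]), p)
    for aj in alpha:
        total += stats.norm.logpdf(aj, loc=0.0, scale=coef_scale)
    total += stats.norm.logpdf(gamma, loc=0.0, scale=coef_scale)
    if family == "linear":
        total += stats.halfcauchy.logpdf(sigma, scale=sigma_scale)
    else:
        total += stats.norm.logpdf(intercept, loc=0.0, scale=coef_scale)
    return float(total)


def grid_posterior_linear(
    y, zp, a, tau2, coef_scale, sigma_scale,
    gamma_grid=None, sigma_grid=None,
):
    """Posterior mean and SD of gamma for the linear model with the latent
    covariate integrated out analytically.

    Marginally each (Y_i, Z_pi) pair is bivariate normal with zero mean and
    covariance [[g^2 + s^2, a g], [a g, a^2 + tau2]]; the two remaining
    parameters are integrated on a dense grid.
    """
    if gamma_grid is None:
        gamma_grid = np.linspace(-8.0, 8.0, 801)
    if sigma_grid is None:
        sigma_grid = np.linspace(0.02, 12.0, 600)
    y = np.asarray(y, float)
    zp = np.asarray(zp, float)
    G, S = np.meshgrid(gamma_grid, sigma_grid, indexing="ij")
    v_y = G**2 + S**2
    v_z = a**2 + tau2
    c_yz = a * G
    det = v_y * v_z - c_yz**2
    n = len(y)
    syy, szz, syz = float(y @ y), float(zp @ zp), float(y @ zp)
    quad = (v_z * syy - 2.0 * c_yz * syz + v_y * szz) / det
    lp = -0.5 * n * np.log(det) - 0.5 * quad
    lp += stats.norm.logpdf(G, scale=coef_scale)
    lp += stats.halfcauchy.logpdf(S, scale=sigma_scale)
    wgt = np.exp(lp - lp.max())
    wgt /= wgt.sum()
    w_gamma = wgt.sum(axis=1)
    mean = float(w_gamma @ gamma_grid)
    sd = float(np.sqrt(w_gamma @ (gamma_grid - mean) ** 2))
    return mean, sd


def importance_posterior_logistic(
    y, zp, a, tau2, coef_scale, n_draws=1_000_000, seed=0
):
    """Posterior mean and SD of gamma for the logistic model by importance
    sampling: (intercept, gamma) drawn from their priors, latent covariates
    from their exact measurement-conditional N(a zp/(a^2+tau2),
    tau2/(a^2+tau2)), weight = Bernoulli likelihood."""
    rng = np.random.default_rng(seed)
    y = np.asarray(y, float)
    zp = np.asarray(zp, float)
    n = len(y)
    v = a**2 + tau2
    z = rng.normal(a * zp / v, np.sqrt(tau2 / v), size=(n_draws, n))
    c = rng.normal(0.0, coef_scale, size=n_draws)
    g = rng.normal(0.0, coef_scale, size=n_draws)
    eta = c[:, None] + g[:, None] * z
    logw = np.sum(y * eta - np.logaddexp(0.0, eta), axis=1)
    w = np.exp(logw - logw.max())
    w /= w.sum()
    mean = float(w @ g)
    sd = float(np.sqrt(w @ (g - mean) ** 2))
    ess = 1.0 / float(w @ w)
    return mean, sd, ess


def centered_slope_and_rss(z, zp):
    """Normal-equations slope of zp on z after centering, plus residual sum
    of squares — the calibration oracle."""
    z = np.asarray(z, float)
    zp = np.asarray(zp, float)
    zc = z - z.mean()
    zpc = zp - zp.mean()
    slope = float(zc @ zpc) / float(zc @ zc)
    resid = zpc - slope * zc
    return slope, float(resid @ resid)
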