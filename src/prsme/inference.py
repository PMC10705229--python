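"""MCMC inference for the measurement-error regression posterior.

The posterior over (coefficients, latent covariate) is sampled natively:

* linear family — blocked Gibbs.  The latent covariate is conditionally
  Gaussian per observation (precision ``a^2/tau^2 + gamma^2/sigma^2 + 1``),
  the coefficient block ``(alpha, gamma)`` is a joint Gaussian conjugate
  update, and ``sigma`` is updated by univariate slice sampling of its
  half-Cauchy-prior conditional.

* logistic family — per-observation Metropolis on the latent covariate
  (Gaussian proposals, scales adapted during warmup only) combined with
  per-coordinate adaptive Metropolis on (intercept, alpha, gamma), target
  acceptance 0.44 per coordinate; or, with ``algorithm="pg_logistic"``,
  Polya-Gamma augmentation making the coefficient block conditionally
  Gaussian (the PG draws use a truncated-series sampler).

Summaries follow the convention of pooling chains for the posterior mean
and the 2.5%/97.5% quantiles, with split-R-hat and rank-normalized ESS as
convergence diagnostics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import arviz as az

from .model_spec import (
    MeasurementModel,
    PriorSpec,
    RegressionData,
    logistic_link,
)

__all__ = ["McmcSettings", "PosteriorSamples", "FitSummary", "fit_bayes", "summarize"]

RHAT_WARN = 1.01
_PG_TRUNCATION = 128  # terms kept in the Polya-Gamma infinite-sum representation


@dataclass(frozen=True)
class McmcSettings:
    """Chain-length and algorithm configuration.

    ``n_iter`` is the total per-chain iteration count including warmup, so
    the default 4 chains x 2000 iterations with 1000 warmup keeps
    4 x 1000 = 4000 draws.
    """

    n_chains: int = 4
    n_iter: int = 2000
    n_warmup: int = 1000
    seed: int = 0
    algorithm: str = "auto"  # auto | gibbs_linear | mh_logistic | pg_logistic

    def __post_init__(self):
        if not (self.n_iter > self.n_warmup >= 1):
            raise ValueError("require n_iter > n_warmup >= 1")
        if self.n_chains < 2:
            raise ValueError("n_chains >= 2 is required for convergence diagnostics")
        if self.algorithm not in ("auto", "gibbs_linear", "mh_logistic", "pg_logistic"):
            raise ValueError(f"unknown algorithm {self.algorithm!r}")

    @property
    def n_kept(self) -> int:
        return self.n_iter - self.n_warmup


@dataclass
class PosteriorSamples:
    """Kept draws, shaped (chains, kept iterations[, dim])."""

    gamma_draws: np.ndarray
    alpha_draws: np.ndarray  # (chains, kept, p)
    sigma_draws: np.ndarray | None = None
    intercept_draws: np.ndarray | None = None
    latent_z_mean: np.ndarray | None = None
    latent_z_sd: np.ndarray | None = None
    latent_z_draws: np.ndarray | None = None

    def __post_init__(self):
        for name in ("gamma_draws", "alpha_draws", "sigma_draws", "intercept_draws"):
            arr = getattr(self, name)
            if arr is not None and not np.all(np.isfinite(arr)):
                raise ValueError(f"{name} contains non-finite draws")


@dataclass
class FitSummary:
    """Point estimate and 95% interval for gamma, with diagnostics and a
    per-parameter summary table (parameter, mean, sd, q2.5, q97.5, rhat, ess)."""

    estimate: float
    ci_low: float
    ci_high: float
    rhat: float = float("nan")
    ess: float = float("nan")
    table: pd.DataFrame | None = None
    method: str = ""


# ----------------------------------------------------------------------
# generic numerical pieces
# ----------------------------------------------------------------------

def _slice_sample(logf, x0, rng, width=1.0, max_steps=50):
    """One univariate slice-sampling update (stepping-out then shrinkage)."""
    y = logf(x0) + np.log(rng.uniform())
    u = rng.uniform()
    lo, hi = x0 - width * u, x0 + width * (1.0 - u)
    for _ in range(max_steps):
        if logf(lo) < y:
            break
        lo -= width
    for _ in range(max_steps):
        if logf(hi) < y:
            break
        hi += width
    while True:
        x1 = rng.uniform(lo, hi)
        if logf(x1) >= y:
            return x1
        if x1 < x0:
            lo = x1
        else:
            hi = x1


def _draw_polya_gamma(rng, c):
    """Approximate PG(1, c) draws via the truncated infinite convolution of
    scaled exponentials; truncation bias is O(1/K) and negligible for the
    coefficient updates this augmentation feeds."""
    c = np.abs(np.asarray(c, dtype=float))
    k = np.arange(1, _PG_TRUNCATION + 1)
    denom = (k - 0.5) ** 2 + (c[..., None] / (2.0 * np.pi)) ** 2
    g = rng.exponential(size=c.shape + (_PG_TRUNCATION,))
    return (g / denom).sum(axis=-1) / (2.0 * np.pi**2)


def _naive_init(data: RegressionData, a: float):
    """Naive-regression initialization: coefficients from least squares of Y
    on [W, Z_p/a] (probit-free working response for logistic), latent Z at
    Z_p/a."""
    z0 = data.noisy_z / a
    X = np.column_stack([np.ones(data.n), data.covariates_w, z0])
    y = data.outcome_y
    if data.family == "logistic":
        y = np.clip(y, 0.05, 0.95)
        y = np.log(y / (1.0 - y))  # rough logit working response
    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    intercept = float(beta[0])
    alpha = beta[1:-1]
    gamma = float(beta[-1])
    resid = y - X @ beta
    sigma = float(max(np.std(resid), 0.05))
    return intercept, alpha, gamma, sigma, z0


# ----------------------------------------------------------------------
# linear family: blocked Gibbs
# ----------------------------------------------------------------------

def _gibbs_linear_chain(data, me, priors, n_iter, n_warmup, rng):
    y, W, zp = data.outcome_y, data.covariates_w, data.noisy_z
    n, p = data.n, data.p
    a, tau2 = me.slope_a, me.resid_var_tau2
    cs2 = priors.coef_scale**2

    _, alpha, gamma, sigma, z = _naive_init(data, a)

    kept = n_iter - n_warmup
    out_gamma = np.empty(kept)
    out_alpha = np.empty((kept, p))
    out_sigma = np.empty(kept)
    z_sum = np.zeros(n)
    z_sq = np.zeros(n)

    eye = np.eye(p + 1)
    for it in range(n_iter):
        s2 = sigma**2
        # latent covariate: independent Gaussians given everything else
        prec = a**2 / tau2 + gamma**2 / s2 + 1.0
        resid_w = y - W @ alpha
        mean = (a * zp / tau2 + gamma * resid_w / s2) / prec
        z = mean + rng.standard_normal(n) / np.sqrt(prec)

        # (alpha, gamma): joint Gaussian conjugate update
        X = np.column_stack([W, z])
        A = X.T @ X / s2 + eye / cs2
        b = X.T @ y / s2
        L = np.linalg.cholesky(A)
        m = np.linalg.solve(A, b)
        beta = m + np.linalg.solve(L.T, rng.standard_normal(p + 1))
        alpha, gamma = beta[:-1], float(beta[-1])
        if not np.isfinite(gamma):
            raise RuntimeError(f"divergence: non-finite draw at iteration {it}")

        # sigma: slice sample on log sigma (half-Cauchy prior conditional)
        rss = float(np.sum((y - X @ beta) ** 2))
        ss = priors.sigma_scale

        def log_target(ls):
            s = np.exp(ls)
            return -n * ls - rss / (2.0 * s * s) - np.log1p((s / ss) ** 2) + ls

        sigma = float(np.exp(_slice_sample(log_target, np.log(sigma), rng)))

        if it >= n_warmup:
            k = it - n_warmup
            out_gamma[k] = gamma
            out_alpha[k] = alpha
            out_sigma[k] = sigma
            z_sum += z
            z_sq += z * z

    z_mean = z_sum / kept
    z_var = np.maximum(z_sq / kept - z_mean**2, 0.0)
    return out_gamma, out_alpha, out_sigma, z_mean, np.sqrt(z_var)


# ----------------------------------------------------------------------
# logistic family: adaptive Metropolis / Polya-Gamma Gibbs
# ----------------------------------------------------------------------

def _bernoulli_loglik_terms(y, eta):
    return y * eta - np.logaddexp(0.0, eta)


def _mh_logistic_chain(data, me, priors, n_iter, n_warmup, rng):
    y, W, zp = data.outcome_y, data.covariates_w, data.noisy_z
    n, p = data.n, data.p
    a, tau2 = me.slope_a, me.resid_var_tau2
    cs2 = priors.coef_scale**2

    intercept, alpha, gamma, _, z = _naive_init(data, a)
    theta = np.concatenate([[intercept], alpha, [gamma]])  # dim d = p + 2
    d = p + 2

    z_step = np.full(n, 0.5)
    th_step = np.full(d, 0.1)
    z_acc = np.zeros(n)
    th_acc = np.zeros(d)
    adapt_block = 50

    def eta_of(theta, z):
        return theta[0] + W @ theta[1:-1] + z * theta[-1]

    kept = n_iter - n_warmup
    out_gamma = np.empty(kept)
    out_alpha = np.empty((kept, p))
    out_int = np.empty(kept)
    z_sum = np.zeros(n)
    z_sq = np.zeros(n)

    eta = eta_of(theta, z)
    ll_obs = _bernoulli_loglik_terms(y, eta)
    lz_obs = -0.5 * ((zp - a * z) ** 2 / tau2 + z * z)

    for it in range(n_iter):
        # latent covariate: independent per-observation Metropolis
        z_prop = z + z_step * rng.standard_normal(n)
        eta_prop = eta + (z_prop - z) * theta[-1]
        ll_prop = _bernoulli_loglik_terms(y, eta_prop)
        lz_prop = -0.5 * ((zp - a * z_prop) ** 2 / tau2 + z_prop * z_prop)
        log_r = (ll_prop + lz_prop) - (ll_obs + lz_obs)
        accept = np.log(rng.uniform(size=n)) < log_r
        z = np.where(accept, z_prop, z)
        eta = np.where(accept, eta_prop, eta)
        ll_obs = np.where(accept, ll_prop, ll_obs)
        lz_obs = np.where(accept, lz_prop, lz_obs)
        z_acc += accept

        # coefficients: per-coordinate random-walk Metropolis
        cols = np.column_stack([np.ones(n), W, z])
        for j in range(d):
            prop = theta[j] + th_step[j] * rng.standard_normal()
            eta_prop = eta + (prop - theta[j]) * cols[:, j]
            ll_prop = _bernoulli_loglik_terms(y, eta_prop)
            log_r = (
                ll_prop.sum()
                - ll_obs.sum()
                - (prop**2 - theta[j] ** 2) / (2.0 * cs2)
            )
            if np.log(rng.uniform()) < log_r:
                theta[j] = prop
                eta = eta_prop
                ll_obs = ll_prop
                th_acc[j] += 1
        if not np.all(np.isfinite(theta)):
            raise RuntimeError(f"divergence: non-finite draw at iteration {it}")

        # proposal adaptation during warmup only (target acceptance 0.44)
        if it < n_warmup and (it + 1) % adapt_block == 0:
            z_step *= np.exp(np.clip(z_acc / adapt_block - 0.44, -0.5, 0.5))
            th_step *= np.exp(np.clip(th_acc / adapt_block - 0.44, -0.5, 0.5))
            z_acc[:] = 0.0
            th_acc[:] = 0.0

        if it >= n_warmup:
            k = it - n_warmup
            out_gamma[k] = theta[-1]
            out_alpha[k] = theta[1:-1]
            out_int[k] = theta[0]
            z_sum += z
            z_sq += z * z

    z_mean = z_sum / kept
    z_var = np.maximum(z_sq / kept - z_mean**2, 0.0)
    return out_gamma, out_alpha, out_int, z_mean, np.sqrt(z_var)


def _pg_logistic_chain(data, me, priors, n_iter, n_warmup, rng):
    y, W, zp = data.outcome_y, data.covariates_w, data.noisy_z
    n, p = data.n, data.p
    a, tau2 = me.slope_a, me.resid_var_tau2
    cs2 = priors.coef_scale**2
    kappa = y - 0.5

    intercept, alpha, gamma, _, z = _naive_init(data, a)
    theta = np.concatenate([[intercept], alpha, [gamma]])
    d = p + 2
    eye = np.eye(d)

    kept = n_iter - n_warmup
    out_gamma = np.empty(kept)
    out_alpha = np.empty((kept, p))
    out_int = np.empty(kept)
    z_sum = np.zeros(n)
    z_sq = np.zeros(n)

    for it in range(n_iter):
        X = np.column_stack([np.ones(n), W, z])
        eta = X @ theta
        omega = np.maximum(_draw_polya_gamma(rng, eta), 1e-12)

        # coefficient block: Gaussian conjugate given omega
        A = (X.T * omega) @ X + eye / cs2
        b = X.T @ kappa
        L = np.linalg.cholesky(A)
        m = np.linalg.solve(A, b)
        theta = m + np.linalg.solve(L.T, rng.standard_normal(d))
        if not np.all(np.isfinite(theta)):
            raise RuntimeError(f"divergence: non-finite draw at iteration {it}")
        gamma = theta[-1]

        # latent covariate: Gaussian given omega (eta linear in z)
        off = theta[0] + W @ theta[1:-1]
        prec = a**2 / tau2 + 1.0 + omega * gamma**2
        mean = (a * zp / tau2 + gamma * (kappa - omega * off)) / prec
        z = mean + rng.standard_normal(n) / np.sqrt(prec)

        if it >= n_warmup:
            k = it - n_warmup
            out_gamma[k] = gamma
            out_alpha[k] = theta[1:-1]
            out_int[k] = theta[0]
            z_sum += z
            z_sq += z * z

    z_mean = z_sum / kept
    z_var = np.maximum(z_sq / kept - z_mean**2, 0.0)
    return out_gamma, out_alpha, out_int, z_mean, np.sqrt(z_var)


# ----------------------------------------------------------------------
# driver
# ----------------------------------------------------------------------

def fit_bayes(
    data: RegressionData,
    me: MeasurementModel,
    priors: PriorSpec = PriorSpec(),
    settings: McmcSettings = McmcSettings(),
) -> PosteriorSamples:
    """Draw MCMC samples from the measurement-error posterior.

    The measurement model must already have ``tau^2 > 0`` (apply
    :meth:`MeasurementModel.floored` first).  Deterministic given
    ``settings.seed``.
    """
    if me.resid_var_tau2 <= 0:
        raise ValueError("resid_var_tau2 must be > 0; apply the variance floor first")
    algo = settings.algorithm
    if algo == "auto":
        algo = "gibbs_linear" if data.family == "linear" else "mh_logistic"
    if (algo == "gibbs_linear") != (data.family == "linear"):
        raise ValueError(f"algorithm {algo!r} does not match family {data.family!r}")

    chain_fn = {
        "gibbs_linear": _gibbs_linear_chain,
        "mh_logistic": _mh_logistic_chain,
        "pg_logistic": _pg_logistic_chain,
    }[algo]

    seeds = np.random.SeedSequence(settings.seed).spawn(settings.n_chains)
    gammas, alphas, extras, zm, zs = [], [], [], [], []
    for ss in seeds:
        rng = np.random.default_rng(ss)
        g, al, ex, m, s = chain_fn(
            data, me, priors, settings.n_iter, settings.n_warmup, rng
        )
        gammas.append(g)
        alphas.append(al)
        extras.append(ex)
        zm.append(m)
        zs.append(s)

    gamma_draws = np.stack(gammas)
    alpha_draws = np.stack(alphas)
    extra_draws = np.stack(extras)
    z_mean = np.mean(zm, axis=0)
    z_sd = np.sqrt(np.mean(np.square(zs), axis=0) + np.var(zm, axis=0))

    if data.family == "linear":
        return PosteriorSamples(
            gamma_draws=gamma_draws,
            alpha_draws=alpha_draws,
            sigma_draws=extra_draws,
            latent_z_mean=z_mean,
            latent_z_sd=z_sd,
        )
    return PosteriorSamples(
        gamma_draws=gamma_draws,
        alpha_draws=alpha_draws,
        intercept_draws=extra_draws,
        latent_z_mean=z_mean,
        latent_z_sd=z_sd,
    )


def _param_row(name, draws):
    pooled = draws.reshape(-1)
    if np.ptp(pooled) == 0.0:
        warnings.warn(
            f"all draws of {name} identical; ESS degenerate", UserWarning, stacklevel=3
        )
        rhat, ess = float("nan"), float("nan")
    else:
        rhat = float(az.rhat(draws))
        ess = float(az.ess(draws))
    return {
        "parameter": name,
        "mean": float(pooled.mean()),
        "sd": float(pooled.std(ddof=1)) if pooled.size > 1 else 0.0,
        "q2.5": float(np.quantile(pooled, 0.025)),
        "q97.5": float(np.quantile(pooled, 0.975)),
        "rhat": rhat,
        "ess": ess,
    }


def summarize(samples: PosteriorSamples) -> FitSummary:
    """Pool chains into the posterior-mean point estimate and the
    2.5%/97.5% credible interval, with split-R-hat and rank-normalized ESS.

    Warns (never fails) when R-hat exceeds 1.01 for any parameter.
    """
    if samples.gamma_draws.size == 0:
        raise ValueError("empty draws")
    if samples.gamma_draws.size < 100:
        raise ValueError("need at least 100 kept draws to summarize")

    rows = [_param_row("gamma", samples.gamma_draws)]
    for j in range(samples.alpha_draws.shape[-1]):
        rows.append(_param_row(f"alpha[{j}]", samples.alpha_draws[..., j]))
    if samples.sigma_draws is not None:
        rows.append(_param_row("sigma", samples.sigma_draws))
    if samples.intercept_draws is not None:
        rows.append(_param_row("intercept", samples.intercept_draws))
    table = pd.DataFrame(rows)

    bad = table[table["rhat"] > RHAT_WARN]
    if len(bad):
        warnings.warn(
            "R-hat above 1.01 for: "
            + ", ".join(f"{r.parameter} ({r.rhat:.3f})" for r in bad.itertuples()),
            UserWarning,
            stacklevel=2,
        )
    g = table.iloc[0]
    return FitSummary(
        estimate=g["mean"],
        ci_low=g["q2.5"],
        ci_high=g["q97.5"],
        rhat=g["rhat"],
        ess=g["ess"],
        table=table,
        method="bayes",
    )
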