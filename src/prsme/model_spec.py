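"""Model definition for the Bayesian PRS measurement-error regression.

The model treats a polygenic risk score (PRS) ``Z_p`` as a noisy, possibly
miscalibrated measurement of a latent true covariate ``Z``:

    Z_p | Z ~ N(a Z, tau^2),      Z ~ N(0, 1)

and relates the outcome ``Y`` to the latent covariate through either a
linear model ``Y = W alpha + Z gamma + eps``, ``eps ~ N(0, sigma^2)``, or a
logistic model ``logit P(Y=1) = c + W alpha + Z gamma``.  Weakly informative
priors are placed on the regression coefficients (zero-mean Gaussian) and,
for the linear family, a half-Cauchy prior on ``sigma``.

This module holds the data containers, the prior specification, and the
unnormalized log joint density that every sampler and oracle evaluates.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import special, stats

__all__ = [
    "FAMILIES",
    "MeasurementModel",
    "PriorSpec",
    "RegressionData",
    "ParameterState",
    "log_joint",
    "logistic_link",
    "VARIANCE_FLOOR_FRACTION",
]

FAMILIES = ("linear", "logistic")

#: Relative floor applied to tau^2 (fraction of Var(Z_p)) when the estimated
#: measurement-error variance is degenerate (perfect PRS).
VARIANCE_FLOOR_FRACTION = 1e-8


def _as_1d(x, name: str) -> np.ndarray:
    arr = np.asarray(x, dtype=float)
    if arr.ndim != 1:
        raise ValueError(f"{name} must be one-dimensional, got shape {arr.shape}")
    if not np.all(np.isfinite(arr)):
        raise ValueError(f"{name} contains non-finite or missing values")
    return arr


@dataclass(frozen=True)
class MeasurementModel:
    """Calibration sub-model of the PRS: slope, residual variance, and the
    size of the validation set the two were estimated on."""

    slope_a: float
    resid_var_tau2: float
    n_validation: int

    def __post_init__(self):
        if not np.isfinite(self.slope_a):
            raise ValueError("slope_a must be finite")
        if self.resid_var_tau2 < 0 or not np.isfinite(self.resid_var_tau2):
            raise ValueError("resid_var_tau2 must be finite and >= 0")
        if self.slope_a**2 + self.resid_var_tau2 <= 0:
            raise ValueError("implied PRS variance a^2 + tau^2 must be positive")

    def floored(self, var_zp: float | None = None) -> "MeasurementModel":
        """Return a copy with ``tau^2`` floored away from zero.

        A perfect PRS (``tau^2 = 0``) makes the measurement density
        degenerate; the floor keeps the sampler defined while collapsing the
        latent covariate onto ``Z_p / a``.
        """
        if var_zp is None:
            var_zp = self.slope_a**2 + self.resid_var_tau2
        floor = VARIANCE_FLOOR_FRACTION * var_zp
        if self.resid_var_tau2 >= floor:
            return self
        warnings.warn(
            f"measurement-error variance tau^2={self.resid_var_tau2:g} below "
            f"floor {floor:g}; flooring (PRS treated as near-noiseless)",
            UserWarning,
            stacklevel=2,
        )
        return replace(self, resid_var_tau2=floor)


@dataclass(frozen=True)
class PriorSpec:
    """Prior scales: SD of the Gaussian prior on coefficients, scale of the
    half-Cauchy prior on the linear residual SD."""

    coef_scale: float = 10.0
    sigma_scale: float = 5.0

    def __post_init__(self):
        if self.coef_scale <= 0 or self.sigma_scale <= 0:
            raise ValueError("prior scales must be positive")


@dataclass(frozen=True)
class RegressionData:
    """Test-set regression inputs.

    ``noisy_z`` holds the PRS for corrected/naive fits, or the true covariate
    for oracle fits.  ``covariates_w`` may have zero columns.
    """

    outcome_y: np.ndarray
    covariates_w: np.ndarray
    noisy_z: np.ndarray
    family: str

    def __post_init__(self):
        y = _as_1d(self.outcome_y, "outcome_y")
        z = _as_1d(self.noisy_z, "noisy_z")
        w = self.covariates_w
        if w is None:
            w = np.empty((len(y), 0))
        w = np.asarray(w, dtype=float)
        if w.ndim == 1:
            w = w[:, None]
        if w.ndim != 2:
            raise ValueError("covariates_w must be a 2-D matrix")
        if not np.all(np.isfinite(w)):
            raise ValueError("covariates_w contains non-finite or missing values")
        if len(y) < 1:
            raise ValueError("outcome_y must have length >= 1")
        if not (len(y) == len(z) == w.shape[0]):
            raise ValueError(
                "length mismatch: outcome_y has "
                f"{len(y)}, noisy_z has {len(z)}, covariates_w has {w.shape[0]} rows"
            )
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}, got {self.family!r}")
        if self.family == "logistic" and not np.all(np.isin(y, (0.0, 1.0))):
            raise ValueError("logistic outcome must be coded 0/1")
        object.__setattr__(self, "outcome_y", y)
        object.__setattr__(self, "covariates_w", w)
        object.__setattr__(self, "noisy_z", z)

    @property
    def n(self) -> int:
        return len(self.outcome_y)

    @property
    def p(self) -> int:
        return self.covariates_w.shape[1]


@dataclass(frozen=True)
class ParameterState:
    """One point in parameter space: coefficients, residual SD (linear
    only), logistic intercept, and the imputed latent covariate."""

    alpha: np.ndarray
    gamma: float
    latent_z: np.ndarray
    sigma: float | None = None
    intercept: float = 0.0

    def __post_init__(self):
        object.__setattr__(self, "alpha", np.atleast_1d(np.asarray(self.alpha, dtype=float)))
        object.__setattr__(self, "latent_z", _as_1d(self.latent_z, "latent_z"))
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be positive when present")


def logistic_link(linear_predictor):
    """Numerically stable inverse-logit; maps 0 to 0.5 and saturates
    gracefully for large inputs."""
    return special.expit(linear_predictor)


def _check_dims(state: ParameterState, data: RegressionData) -> None:
    if len(state.latent_z) != data.n:
        raise ValueError(
            f"latent_z has length {len(state.latent_z)} but data has {data.n} observations"
        )
    if len(state.alpha) != data.p:
        raise ValueError(
            f"alpha has length {len(state.alpha)} but covariates_w has {data.p} columns"
        )
    if data.family == "linear" and state.sigma is None:
        raise ValueError("sigma is required for the linear family")


def log_joint(
    state: ParameterState,
    data: RegressionData,
    me: MeasurementModel,
    priors: PriorSpec,
) -> float:
    """Unnormalized log posterior density of the full model.

    Sums the measurement density of ``Z_p`` given ``a Z, tau^2``, the
    standard-normal density of the latent covariate, the outcome
    log-likelihood, and the log priors on the coefficients (plus the
    half-Cauchy prior on ``sigma`` for the linear family and the intercept
    prior for the logistic family).  Finite for any finite state.
    """
    _check_dims(state, data)
    if me.resid_var_tau2 <= 0:
        raise ValueError("resid_var_tau2 must be > 0; apply the variance floor first")
    z = state.latent_z
    tau = np.sqrt(me.resid_var_tau2)

    lp = stats.norm.logpdf(data.noisy_z, loc=me.slope_a * z, scale=tau).sum()
    lp += stats.norm.logpdf(z).sum()

    eta = data.covariates_w @ state.alpha + z * state.gamma
    if data.family == "linear":
        lp += stats.norm.logpdf(data.outcome_y, loc=eta, scale=state.sigma).sum()
        lp += stats.halfcauchy.logpdf(state.sigma, scale=priors.sigma_scale)
    else:
        eta = eta + state.intercept
        # Bernoulli log-likelihood on the log-odds scale, stable for |eta| large
        lp += float(np.sum(data.outcome_y * eta - np.logaddexp(0.0, eta)))
        lp += stats.norm.logpdf(state.intercept, scale=priors.coef_scale)

    lp += stats.norm.logpdf(state.alpha, scale=priors.coef_scale).sum()
    lp += stats.norm.logpdf(state.gamma, scale=priors.coef_scale)
    return float(lp)
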