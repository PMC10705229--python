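"""Synthetic-data generation at two tiers.

The *latent* tier draws data exactly from the assumed model: a standard
normal true covariate, a PRS ``Z_p = a Z + e`` with Gaussian error, and a
linear or logistic outcome.  The *genotype* tier builds the covariate from
simulated SNP genotypes with a spike-and-slab genetic architecture,
estimates per-SNP weights by marginal GWAS regression in a training set,
and scores a PRS in the validation and test sets — so the Gaussian
measurement-error model is an emergent property rather than an assumption,
and the realized calibration slope and residual variance are reported.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .calibration import ValidationData, estimate_measurement_model
from .model_spec import MeasurementModel, RegressionData, logistic_link

__all__ = [
    "LatentSimConfig",
    "GenotypeSimConfig",
    "SimulatedData",
    "simulate_latent",
    "simulate_genotype_tier",
]


@dataclass(frozen=True)
class LatentSimConfig:
    """Direct-tier configuration: sizes, true effect, measurement model."""

    n_test: int = 2000
    n_validation: int = 2000
    gamma_true: float = 0.3
    family: str = "linear"
    slope_a: float = 1.0
    resid_var_tau2: float = 1.0
    seed: int = 0

    def __post_init__(self):
        if self.n_test < 10:
            raise ValueError("n_test must be >= 10")
        if self.n_validation < 3:
            raise ValueError("n_validation must be >= 3")
        if self.resid_var_tau2 < 0:
            raise ValueError("resid_var_tau2 must be >= 0")
        if self.family not in ("linear", "logistic"):
            raise ValueError(f"unknown family {self.family!r}")


@dataclass(frozen=True)
class GenotypeSimConfig:
    """Genotype-tier configuration at desk scale.

    Defaults use 1,000 independent SNPs and 2,000 individuals per set; the
    heritability (0.5) and causal fraction (0.01) follow the spike-and-slab
    architecture ``beta_j ~ pi N(0, h^2/(M pi)) + (1 - pi) delta_0``.
    """

    n_snps: int = 1000
    heritability: float = 0.5
    causal_fraction: float = 0.01
    n_train: int = 2000
    n_validation: int = 2000
    n_test: int = 2000
    maf_range: tuple = (0.05, 0.5)
    seed: int = 0

    def __post_init__(self):
        if not (0.0 < self.heritability < 1.0):
            raise ValueError("heritability must be in (0, 1)")
        if not (0.0 < self.causal_fraction <= 1.0):
            raise ValueError("causal_fraction must be in (0, 1]")
        lo, hi = self.maf_range
        if not (0.0 < lo <= hi < 0.5) and not (0.0 < lo <= hi == 0.5):
            raise ValueError("maf_range must satisfy 0 < lo <= hi <= 0.5")


@dataclass
class SimulatedData:
    """Bundle returned by both tiers: the test-set regression data (PRS in
    ``noisy_z``), the hidden true covariate, the validation pairs, the true
    effect, and — for the genotype tier — the realized measurement model."""

    test: RegressionData
    true_z: np.ndarray
    validation: ValidationData
    gamma_true: float
    realized_me: MeasurementModel | None = None
    snp_weights: np.ndarray | None = None


def _draw_outcome(rng, z, gamma, family):
    if family == "linear":
        return z * gamma + rng.standard_normal(len(z))
    return rng.binomial(1, logistic_link(z * gamma)).astype(float)


def simulate_latent(cfg: LatentSimConfig) -> SimulatedData:
    """Draw test and validation data directly from the assumed model.

    ``Z ~ N(0,1)`` i.i.d.; ``Z_p = a Z + e`` with ``e ~ N(0, tau^2)``;
    linear ``Y = Z gamma + N(0,1)``, logistic ``Y ~ Ber(expit(Z gamma))``.
    Validation pairs are drawn independently from the same (Z, Z_p) law.
    Deterministic given ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    tau = np.sqrt(cfg.resid_var_tau2)

    z = rng.standard_normal(cfg.n_test)
    zp = cfg.slope_a * z + tau * rng.standard_normal(cfg.n_test)
    y = _draw_outcome(rng, z, cfg.gamma_true, cfg.family)

    zv = rng.standard_normal(cfg.n_validation)
    zpv = cfg.slope_a * zv + tau * rng.standard_normal(cfg.n_validation)

    test = RegressionData(
        outcome_y=y, covariates_w=None, noisy_z=zp, family=cfg.family
    )
    return SimulatedData(
        test=test,
        true_z=z,
        validation=ValidationData(true_z=zv, prs_zp=zpv),
        gamma_true=cfg.gamma_true,
    )


def _draw_genotypes(rng, freqs, n):
    return rng.binomial(2, freqs, size=(n, len(freqs))).astype(float)


def simulate_genotype_tier(
    cfg: GenotypeSimConfig, gamma_true: float, family: str = "linear"
) -> SimulatedData:
    """Genotype-level generative process at reduced SNP count.

    Per-SNP allele frequencies are uniform on ``maf_range``; genotypes are
    Binomial(2, f) and column-standardized with the training-set
    standardizer (frozen, then re-applied to validation and test).  Causal
    effects follow the spike-and-slab prior; environmental noise is scaled
    so the realized genetic variance fraction equals the target
    heritability.  GWAS marginal effects are estimated per SNP in the
    training set and shrunken by the ridge-style factor
    ``n_train / (n_train + M/h^2)`` to form scoring weights; the PRS is the
    weighted genotype sum in each set.
    """
    if family not in ("linear", "logistic"):
        raise ValueError(f"unknown family {family!r}")
    rng = np.random.default_rng(cfg.seed)
    M = cfg.n_snps

    freqs = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=M)
    X_train = _draw_genotypes(rng, freqs, cfg.n_train)
    for attempt in range(11):
        mono = X_train.std(axis=0) == 0.0
        if not mono.any():
            break
        if attempt == 10:
            warnings.warn(
                f"{mono.sum()} SNP column(s) still monomorphic after 10 resampling "
                "attempts; raising their allele frequency",
                UserWarning,
                stacklevel=2,
            )
            freqs[mono] = 0.5
        freqs[mono] = rng.uniform(cfg.maf_range[0], cfg.maf_range[1], size=mono.sum())
        X_train[:, mono] = _draw_genotypes(rng, freqs[mono], cfg.n_train)

    mu, sd = X_train.mean(axis=0), X_train.std(axis=0)

    def standardize(X):
        return (X - mu) / sd

    Xs_train = standardize(X_train)

    # spike-and-slab causal architecture
    causal = rng.uniform(size=M) < cfg.causal_fraction
    beta = np.zeros(M)
    beta[causal] = rng.normal(
        0.0, np.sqrt(cfg.heritability / (M * cfg.causal_fraction)), size=causal.sum()
    )

    def covariate(Xs):
        g = Xs @ beta
        var_g = g.var()
        if var_g == 0.0:  # no causal SNP drawn — pure noise covariate
            return rng.standard_normal(len(g)), g
        noise_sd = np.sqrt(var_g * (1.0 - cfg.heritability) / cfg.heritability)
        return g + noise_sd * rng.standard_normal(len(g)), g

    z_train, _ = covariate(Xs_train)
    # marginal GWAS betas in the training set, one SNP at a time
    beta_hat = (Xs_train.T @ z_train) / np.maximum((Xs_train**2).sum(axis=0), 1.0)
    shrink = cfg.n_train / (cfg.n_train + M / cfg.heritability)
    weights = shrink * beta_hat

    X_val = _draw_genotypes(rng, freqs, cfg.n_validation)
    X_test = _draw_genotypes(rng, freqs, cfg.n_test)
    Xs_val, Xs_test = standardize(X_val), standardize(X_test)
    z_val, _ = covariate(Xs_val)
    z_test, _ = covariate(Xs_test)

    # put the covariate on the N(0,1) scale the outcome model assumes,
    # using the training-set standardizer for Z as well
    z_scale = z_train.std()
    z_val = z_val / z_scale
    z_test = z_test / z_scale

    zp_val = Xs_val @ weights / z_scale
    zp_test = Xs_test @ weights / z_scale

    y = _draw_outcome(rng, z_test, gamma_true, family)
    validation = ValidationData(true_z=z_val, prs_zp=zp_val)
    realized = estimate_measurement_model(validation)
    test = RegressionData(outcome_y=y, covariates_w=None, noisy_z=zp_test, family=family)
    return SimulatedData(
        test=test,
        true_z=z_test,
        validation=validation,
        gamma_true=gamma_true,
        realized_me=realized,
        snp_weights=weights,
    )
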