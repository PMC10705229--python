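"""Estimation of the PRS measurement-error sub-model from validation data.

A small validation set holds paired observations of the true covariate ``Z``
and its PRS ``Z_p``.  Regressing ``Z_p`` on ``Z`` (through the origin after
centering) yields the calibration slope ``a`` and residual variance
``tau^2`` that the Bayesian outcome model plugs in.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .model_spec import MeasurementModel, _as_1d

__all__ = ["ValidationData", "estimate_measurement_model", "reliability"]


@dataclass(frozen=True)
class ValidationData:
    """Paired true covariate and PRS for S validation individuals."""

    true_z: np.ndarray
    prs_zp: np.ndarray

    def __post_init__(self):
        z = _as_1d(self.true_z, "true_z")
        zp = _as_1d(self.prs_zp, "prs_zp")
        if len(z) != len(zp):
            raise ValueError(
                f"length mismatch: true_z has {len(z)}, prs_zp has {len(zp)}"
            )
        if len(z) < 3:
            raise ValueError("validation set must have S >= 3 pairs")
        if np.var(z) <= 0:
            raise ValueError("degenerate validation covariate: true_z has zero variance")
        object.__setattr__(self, "true_z", z)
        object.__setattr__(self, "prs_zp", zp)

    @property
    def n(self) -> int:
        return len(self.true_z)


def estimate_measurement_model(
    v: ValidationData, standardize: bool = False, ddof: int = 1
) -> MeasurementModel:
    """Least-squares fit of ``Z_p = a Z + e`` on the validation pairs.

    Both columns are centered (the no-intercept regression is then exact);
    with ``standardize`` the true covariate is additionally scaled to unit
    variance, matching the convention used for the test-set covariates.
    ``Z_p`` is never rescaled here — it must stay on the scale the test-set
    fit will see, via a single shared standardizer if any.

    The residual variance uses denominator ``S - ddof`` (default ``S - 1``:
    one slope parameter after centering).
    """
    z = v.true_z - v.true_z.mean()
    zp = v.prs_zp - v.prs_zp.mean()
    if standardize:
        z = z / z.std(ddof=1)
    s2 = float(z @ z)
    slope = float(z @ zp) / s2
    resid = zp - slope * z
    tau2 = float(resid @ resid) / (v.n - ddof)
    return MeasurementModel(slope_a=slope, resid_var_tau2=max(tau2, 0.0), n_validation=v.n)


def reliability(me: MeasurementModel) -> float:
    """Squared correlation between PRS and true covariate, a^2/(a^2 + tau^2),
    under Var(Z) = 1.  Equals 1 iff tau^2 = 0; governs attenuation."""
    a2 = me.slope_a**2
    return a2 / (a2 + me.resid_var_tau2)
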