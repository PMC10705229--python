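"""Non-Bayesian reference strategies: oracle and naive regression fits.

The oracle strategy regresses the outcome on the true covariate; the naive
strategy regresses it on the PRS without correction.  Both are ordinary
least-squares / maximum-likelihood fits with Wald 95% intervals.  The
closed-form attenuation factor for the naive linear slope is also provided
for property checks: with Var(Z) = 1 the naive slope converges to
``gamma * a / (a^2 + tau^2)``.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
import statsmodels.api as sm
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

from .model_spec import MeasurementModel, RegressionData
from .inference import FitSummary

__all__ = ["fit_uncorrected", "attenuation_factor"]


def fit_uncorrected(data: RegressionData) -> FitSummary:
    """Plain regression of Y on (W, noisy_z) with an intercept.

    Linear: least squares with Wald 95% CI.  Logistic: Newton maximum
    likelihood; perfect separation triggers a warning and a capped
    quasi-Newton refit rather than failure.  The reported coefficient is the
    one on ``noisy_z``.
    """
    X = np.column_stack([data.covariates_w, data.noisy_z])
    X = sm.add_constant(X, has_constant="add")
    names = ["intercept"] + [f"alpha[{j}]" for j in range(data.p)] + ["gamma"]

    if data.family == "linear":
        rank = np.linalg.matrix_rank(X)
        if rank < X.shape[1]:
            raise ValueError("singular design matrix in linear fit")
        res = sm.OLS(data.outcome_y, X).fit()
    else:
        model = sm.Logit(data.outcome_y, X)
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", PerfectSeparationWarning)
                res = model.fit(method="newton", tol=1e-8, maxiter=100, disp=False)
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            warnings.warn(
                "perfect separation detected in logistic fit; "
                "falling back to capped quasi-Newton iterations",
                UserWarning,
                stacklevel=2,
            )
            res = model.fit(method="lbfgs", maxiter=50, disp=False)

    est = np.asarray(res.params, dtype=float)
    se = np.asarray(res.bse, dtype=float)
    lo, hi = est - 1.959963984540054 * se, est + 1.959963984540054 * se
    table = pd.DataFrame(
        {
            "parameter": names,
            "mean": est,
            "sd": se,
            "q2.5": lo,
            "q97.5": hi,
            "rhat": np.nan,
            "ess": np.nan,
        }
    )
    return FitSummary(
        estimate=float(est[-1]),
        ci_low=float(lo[-1]),
        ci_high=float(hi[-1]),
        table=table,
        method="uncorrected",
    )


def attenuation_factor(me: MeasurementModel) -> float:
    """Large-n multiplicative bias of the naive linear slope on the PRS:
    ``a / (a^2 + tau^2)`` with Var(Z) = 1.  Equals 1 for a perfect PRS.
    Linear-family only; logistic attenuation has no exact closed form."""
    return me.slope_a / (me.slope_a**2 + me.resid_var_tau2)
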