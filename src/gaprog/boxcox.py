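"""Box-Cox transformation machinery and AIC-based selection of lambda.

The lesion size y (mm^2, strictly positive) is transformed by the
power family

    f_lambda(y) = (y^lambda - 1) / lambda   (lambda != 0)
    f_0(y)      = log(y)

before mixed-model fitting; lambda = 1 corresponds to linear growth of
the area, lambda = 0.5 to linear growth of an effective radius
(square-root model) and lambda = 0 to exponential growth. Models
fitted at different lambda are compared on the *original* scale by
adding the log-Jacobian (lambda - 1) * sum(log y) to the transformed-
scale log-likelihood (density transformation theorem), so that the
AIC values are comparable across lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd

from .data_model import CohortData

__all__ = [
    "transform",
    "inverse_transform",
    "loglik_original_scale",
    "default_grid",
    "GridSearchResult",
    "grid_search",
]


def transform(y, lam: float):
    """Box-Cox transform of positive sizes; scalar in -> scalar out.

    Raises ValueError if any y <= 0 (outside the transform's domain).
    """
    arr = np.asarray(y, dtype=float)
    if np.any(~(arr > 0)):
        raise ValueError("Box-Cox transform requires y > 0")
    if lam == 0.0:
        out = np.log(arr)
    else:
        out = np.expm1(lam * np.log(arr)) / lam
    return out if arr.ndim else float(out)


def inverse_transform(z, lam: float):
    """Inverse Box-Cox transform; NaN marks an undefined inverse.

    For lambda != 0 the inverse (lambda*z + 1)^(1/lambda) exists only
    when lambda*z + 1 > 0; outside that domain NaN is returned (a
    value, not an error). For lambda = 0 the inverse exp(z) always
    exists.
    """
    arr = np.asarray(z, dtype=float)
    if lam == 0.0:
        out = np.exp(arr)
    else:
        lz = lam * arr
        with np.errstate(invalid="ignore", divide="ignore"):
            # log1p keeps the lambda -> 0 limit exact (exp(z))
            out = np.where(lz > -1.0, np.exp(np.log1p(np.maximum(lz, -1.0 + 1e-300)) / lam), np.nan)
    return out if arr.ndim else float(out)


def loglik_original_scale(loglik_transformed: float, lam: float, y_all) -> float:
    """Jacobian-corrected log-likelihood on the original mm^2 scale.

    log L_y = log L_z + (lambda - 1) * sum(log y); equals log L_z at
    lambda = 1 (unit Jacobian).
    """
    y = np.asarray(y_all, dtype=float)
    if np.any(~(y > 0)):
        raise ValueError("Jacobian correction requires y > 0")
    return float(loglik_transformed + (lam - 1.0) * np.sum(np.log(y)))


def default_grid() -> np.ndarray:
    """Default lambda grid: 0 (log model) plus 0.05 .. 1.50 in steps of 0.05."""
    return np.round(np.concatenate(([0.0], np.arange(1, 31) * 0.05)), 10)


@dataclass
class GridSearchResult:
    """Per-lambda fits, Jacobian-corrected AICs and the AIC-minimizing lambda."""

    lambdas: np.ndarray
    loglik: np.ndarray  # Jacobian-corrected log-likelihood per lambda (NaN on failure)
    aic: np.ndarray  # AIC on the original-y scale per lambda (NaN on failure)
    lambda_opt: float
    fits: list  # ModelFit per lambda (None where the fit failed)
    errors: dict[float, str] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        """Two-column (lambda, AIC) table, e.g. for plotting the AIC profile."""
        return pd.DataFrame({"lambda": self.lambdas, "aic": self.aic})

    @property
    def best_fit(self):
        i = int(np.nanargmin(self.aic))
        return self.fits[i]


def grid_search(
    data: CohortData,
    grid: Sequence[float] | None = None,
    with_covariables: bool = False,
    fit_settings: dict[str, Any] | None = None,
) -> GridSearchResult:
    """Fit the mixed model at each lambda on the grid and select by AIC.

    For every lambda the response is transformed, the model (with or
    without covariables) is fitted by maximum likelihood, and the AIC
    is computed on the original scale using the Jacobian correction.
    Ties in AIC are broken toward the smaller lambda (the grid is
    sorted ascending and the first minimum is taken). Individual fit
    failures are recorded per lambda and are fatal only if every
    lambda fails.

    Warm starts: the variance-ratio and working-covariable solutions
    of the previous grid point seed the next one; the fixed point of
    the iterative algorithm does not depend on its starting value.
    """
    from . import constrained_lmm as clmm  # local import: avoids module cycle

    if grid is None:
        grid = default_grid()
    lambdas = np.sort(np.unique(np.asarray(list(grid), dtype=float)))
    if lambdas.size == 0:
        raise ValueError("empty lambda grid")
    settings = dict(fit_settings or {})

    logliks = np.full(lambdas.size, np.nan)
    aics = np.full(lambdas.size, np.nan)
    fits: list = [None] * lambdas.size
    errors: dict[float, str] = {}

    rho_start = None
    xtilde_start = None
    for i, lam in enumerate(lambdas):
        try:
            if with_covariables:
                spec = clmm.ModelSpec(
                    with_covariables=True,
                    covariable_names=list(data.covariable_names),
                    lam=float(lam),
                    **{
                        k: settings[k]
                        for k in ("include_stability_intercept", "onset_threshold_mm2")
                        if k in settings
                    },
                )
                fit = clmm.fit_with_covariables(
                    data,
                    spec,
                    tol=settings.get("tol", 1e-6),
                    max_iter=settings.get("max_iter", 50),
                    init=xtilde_start,
                    rho_start=rho_start,
                )
                xtilde_start = fit.xtilde
            else:
                fit = clmm.fit_no_covariables(data, float(lam), rho_start=rho_start)
            fits[i] = fit
            logliks[i] = fit.loglik_y
            aics[i] = fit.aic_y
            if fit.sigma_eps > 0:
                rho_start = (
                    np.log(max(fit.sigma_zeta / fit.sigma_eps, 1e-8) ** 2),
                    np.log(max(fit.sigma_Delta / fit.sigma_eps, 1e-8) ** 2),
                )
        except Exception as exc:  # noqa: BLE001 - recorded, not fatal
            errors[float(lam)] = f"{type(exc).__name__}: {exc}"

    if np.all(np.isnan(aics)):
        raise RuntimeError(f"model fit failed at every lambda: {errors}")
    lambda_opt = float(lambdas[int(np.nanargmin(aics))])
    return GridSearchResult(
        lambdas=lambdas,
        loglik=logliks,
        aic=aics,
        lambda_opt=lambda_opt,
        fits=fits,
        errors=errors,
    )
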