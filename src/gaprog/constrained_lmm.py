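"""Disease-age-parameterized linear mixed-effects models for GA growth.

The transformed lesion size z = f_lambda(y) of eye i in patient j at
follow-up time t is modeled as a linear trajectory in *disease age*
Delta_i + t, where Delta_i (the unobserved time since onset at study
entry) is normally distributed across eyes with mean mu_Delta.

Without covariables this reduces to an ordinary nested mixed model

    z_ijt = mu_theta + beta*t + zeta_j + alpha_i + eps_ijt,

with patient effects zeta_j ~ N(0, sigma_zeta^2), eye-within-patient
effects alpha_i ~ N(0, sigma_theta^2) and residuals eps ~ N(0, sigma^2).

With covariables x_i the per-eye enlargement rate becomes
beta + beta_x' x_i, and the implied model

    z_ijt = (beta + beta_x' x_i) * (mu_Delta + gamma_i + zeta_j + t) + eps_ijt

carries hard constraints tying the slope of t, the slopes of x_i*t and
the loadings of both random effects to the same quantities. It is
fitted by the iterative working-covariable algorithm: given current
estimates, compute xt_i = beta + beta_x' x_i, then fit the *linear*
mixed model

    z_ijt = c0 + beta*t + beta_x' x_i t + mu_Delta*xt_i
            + xt_i*gamma_i + xt_i*zeta_j + eps_ijt

in which xt_i is a known per-eye loading, and iterate until the
coefficients stop changing. A fixed intercept c0 is included for
numerical stability (it relaxes the implicit zero-mean constraint on
the estimated random effects) and is reported.

Inner fits maximize the Gaussian marginal likelihood directly, per
patient block, profiling the fixed effects by generalized least
squares given the two variance ratios; this keeps the known-loading
random-effect structure exact. A brute-force optimizer over the fully
constrained likelihood (`brute_force_ml`) is exposed as an independent
cross-check for small cohorts.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize

from . import boxcox
from .data_model import CohortData

__all__ = [
    "ModelSpec",
    "ModelFit",
    "FitError",
    "fit_model",
    "fit_no_covariables",
    "fit_with_covariables",
    "brute_force_ml",
    "conditional_modes",
    "residual_diagnostics",
    "linear_predictor",
    "fit_summary_dict",
    "fit_summary_text",
]

#: Variance components smaller than this SD are reported as exactly 0
#: with a boundary flag.
BOUNDARY_SD = 1e-6

#: Floor for the profiled residual variance (guards exactly noiseless data).
_SIGMA2_FLOOR = 1e-12


class FitError(RuntimeError):
    """Likelihood optimization failed; the message carries the trace."""


@dataclass
class ModelSpec:
    """What to fit: covariables, transformation, intercept, onset threshold."""

    with_covariables: bool = False
    covariable_names: list[str] = field(default_factory=list)
    lam: float = 0.45
    # A free fixed intercept in the working-covariable model is nearly
    # collinear with the working covariable itself (whose spread across
    # eyes is small when covariable effects are modest) and then destroys
    # the identifiability of mu_Delta; with exact closed-form GLS inner
    # fits it is not needed for numerical stability, so it is off by
    # default and available as an option.
    include_stability_intercept: bool = False
    onset_threshold_mm2: float = 0.05

    def __post_init__(self) -> None:
        if self.with_covariables != bool(self.covariable_names):
            raise ValueError(
                "covariable_names must be nonempty iff with_covariables"
            )
        if self.onset_threshold_mm2 <= 0:
            raise ValueError("onset_threshold_mm2 must be positive")


@dataclass
class ModelFit:
    """Maximum-likelihood fit of the (possibly constrained) mixed model."""

    spec: ModelSpec
    beta: float
    beta_x: dict[str, float]
    mu_Delta: float | None  # covariable model: mean disease age at entry (years)
    mu_theta: float | None  # no-covariable model: fixed intercept (z units)
    intercept0: float  # stability intercept (z units; 0 when disabled/dropped)
    sigma_Delta: float  # eye-level random-effect SD (years in the covariable model)
    sigma_zeta: float  # patient-level random-effect SD
    sigma_eps: float  # residual SD (z units)
    xtilde: dict[tuple[str, str], float]  # eye -> working covariable / RE loading
    zeta_hat: dict[str, float] | None  # patient -> conditional mode
    gamma_hat: dict[tuple[str, str], float] | None  # eye -> conditional mode
    fitted_z: np.ndarray | None  # per data row, includes random effects
    residuals: np.ndarray | None  # z - fitted_z, per data row
    loglik_z: float
    loglik_y: float
    aic_y: float
    n_params: int
    n_iterations: int
    converged: bool
    boundary: list[str] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    coef_trace: list[dict[str, float]] = field(default_factory=list)


# ---------------------------------------------------------------------------
# grouping and profiled marginal likelihood
# ---------------------------------------------------------------------------


class _Groups:
    """Row bookkeeping: patient blocks and eye sub-blocks, in row order."""

    def __init__(self, df: pd.DataFrame):
        pid = df["patient_id"].to_numpy()
        eid = df["eye_id"].to_numpy()
        self.n = len(df)
        self.patients: list[str] = []
        self.patient_rows: list[np.ndarray] = []
        self.patient_eyes: list[list[tuple[str, str]]] = []
        self.eye_rows: list[list[np.ndarray]] = []  # local (within-block) indices
        order: dict[str, int] = {}
        for r, p in enumerate(pid):
            if p not in order:
                order[p] = len(self.patients)
                self.patients.append(p)
        rows_by_p: list[list[int]] = [[] for _ in self.patients]
        for r, p in enumerate(pid):
            rows_by_p[order[p]].append(r)
        for jp, rows in enumerate(rows_by_p):
            rows_arr = np.asarray(rows, dtype=int)
            self.patient_rows.append(rows_arr)
            eyes: dict[tuple[str, str], list[int]] = {}
            for local, r in enumerate(rows_arr):
                eyes.setdefault((pid[r], eid[r]), []).append(local)
            self.patient_eyes.append(list(eyes))
            self.eye_rows.append([np.asarray(v, dtype=int) for v in eyes.values()])
        self.max_eyes = max(len(e) for e in self.patient_eyes)
        self.eye_keys: list[tuple[str, str]] = [
            k for eyes in self.patient_eyes for k in eyes
        ]


class _ProfiledLMM:
    """Marginal Gaussian likelihood profiled over fixed effects and sigma^2.

    For fixed variance ratios rho = (sigma_zeta^2, sigma_re^2) / sigma^2
    the per-patient correlation matrix is

        Lambda_j = I + rho_zeta * u u' + rho_re * sum_e u_e u_e',

    where u holds the per-row random-effect loadings (the working
    covariable, or 1) and u_e its restriction to eye e. Fixed effects
    are profiled by GLS and sigma^2 in closed form, leaving a
    2-parameter optimization. Rank-1 structure is exploited via the
    Woodbury identity with per-patient q x q cores (q = 1 + max eyes
    per patient), batched across patients.
    """

    def __init__(self, groups: _Groups, X: np.ndarray, z: np.ndarray, u: np.ndarray):
        self.g = groups
        self.n, self.p = X.shape
        q = 1 + groups.max_eyes
        self.q = q
        J = len(groups.patients)
        self.UtU = np.zeros((J, q, q))
        self.UtX = np.zeros((J, q, self.p))
        self.Utz = np.zeros((J, q))
        self.XtX = X.T @ X
        self.Xtz = X.T @ z
        self.ztz = float(z @ z)
        self.X = X
        self.z = z
        self.u = u
        for j, rows in enumerate(groups.patient_rows):
            uj = u[rows]
            U = np.zeros((rows.size, q))
            U[:, 0] = uj
            for e, local in enumerate(groups.eye_rows[j]):
                U[local, 1 + e] = uj[local]
            self.UtU[j] = U.T @ U
            self.UtX[j] = U.T @ X[rows]
            self.Utz[j] = U.T @ z[rows]

    def _s_vector(self, log_rho: np.ndarray) -> np.ndarray:
        lr = np.clip(log_rho, -40.0, 40.0)
        s = np.empty(self.q)
        s[0] = math.exp(0.5 * lr[0])  # patient effect
        s[1:] = math.exp(0.5 * lr[1])  # eye effects
        return s

    def _gls(self, log_rho: np.ndarray):
        s = self._s_vector(log_rho)
        S2 = np.outer(s, s)
        K = np.eye(self.q)[None, :, :] + S2[None, :, :] * self.UtU
        L = np.linalg.cholesky(K)
        logdet = 2.0 * float(np.sum(np.log(np.diagonal(L, axis1=1, axis2=2))))
        TX = s[None, :, None] * self.UtX
        Tz = s[None, :] * self.Utz
        WX = np.linalg.solve(K, TX)
        Wz = np.linalg.solve(K, Tz[..., None])[..., 0]
        A = self.XtX - np.einsum("jqp,jqr->pr", TX, WX)
        b_rhs = self.Xtz - np.einsum("jqp,jq->p", TX, Wz)
        ztLz = self.ztz - float(np.einsum("jq,jq->", Tz, Wz))
        try:
            coefs = np.linalg.solve(A, b_rhs)
        except np.linalg.LinAlgError:
            coefs = np.linalg.lstsq(A, b_rhs, rcond=None)[0]
        rss = ztLz - float(coefs @ b_rhs)
        sigma2 = max(rss / self.n, _SIGMA2_FLOOR)
        return coefs, sigma2, logdet, A

    def neg_loglik(self, log_rho: np.ndarray) -> float:
        try:
            _, sigma2, logdet, _ = self._gls(log_rho)
        except np.linalg.LinAlgError:
            return 1e100
        return 0.5 * (self.n * math.log(2.0 * math.pi * sigma2) + logdet + self.n)

    def fit(self, rho_start=None):
        starts = []
        if rho_start is not None:
            starts.append(np.asarray(rho_start, dtype=float))
        starts.extend([np.array([2.0, 1.0]), np.array([-2.0, -2.0])])
        best = None
        for x0 in starts:
            res = optimize.minimize(
                self.neg_loglik,
                x0,
                method="Nelder-Mead",
                options={"xatol": 1e-6, "fatol": 1e-10, "maxiter": 600},
            )
            if best is None or res.fun < best.fun:
                best = res
            if rho_start is not None:
                break  # warm start: single descent is enough
        if best is None or not np.isfinite(best.fun):
            raise FitError(f"inner variance optimization failed: {best}")
        log_rho = best.x
        coefs, sigma2, logdet, _ = self._gls(log_rho)
        loglik = -float(best.fun)
        return {
            "log_rho": log_rho,
            "coefs": coefs,
            "sigma2": sigma2,
            "loglik": loglik,
            "nfev": best.nfev,
        }

    def conditional_modes(self, log_rho, coefs):
        """Posterior modes of (zeta_j, gamma_i) at plugged-in ML parameters."""
        s = self._s_vector(log_rho)
        rho_z, rho_e = s[0] ** 2, s[1] ** 2 if self.q > 1 else 0.0
        resid = self.z - self.X @ coefs
        zeta: dict[str, float] = {}
        gamma: dict[tuple[str, str], float] = {}
        for j, rows in enumerate(self.g.patient_rows):
            uj = self.u[rows]
            Lam = np.eye(rows.size) + rho_z * np.outer(uj, uj)
            for local in self.g.eye_rows[j]:
                Lam[np.ix_(local, local)] += rho_e * np.outer(uj[local], uj[local])
            try:
                w = np.linalg.solve(Lam, resid[rows])
            except np.linalg.LinAlgError as exc:
                raise FitError(
                    f"singular covariance block for patient "
                    f"{self.g.patients[j]!r}"
                ) from exc
            zeta[self.g.patients[j]] = float(rho_z * (uj @ w))
            for key, local in zip(self.g.patient_eyes[j], self.g.eye_rows[j]):
                gamma[key] = float(rho_e * (uj[local] @ w[local]))
        return zeta, gamma


# ---------------------------------------------------------------------------
# design construction
# ---------------------------------------------------------------------------


def _covariable_matrix(data: CohortData) -> np.ndarray:
    return data.df[list(data.covariable_names)].to_numpy(dtype=float)


def _build_design(
    t: np.ndarray,
    Xc: np.ndarray,
    xt: np.ndarray,
    include_intercept: bool,
):
    """Columns of the working-covariable model: [1?, t, x*t..., xt].

    The intercept column is dropped when the working covariable is
    (numerically) constant across eyes, where it would be collinear
    with the xt column — in particular at the xt = 1 initialization.
    Returns (X, labels, intercept_used).
    """
    intercept_used = include_intercept and (np.ptp(xt) > 1e-8 * (1 + np.max(np.abs(xt))))
    cols = []
    labels = []
    if intercept_used:
        cols.append(np.ones_like(t))
        labels.append("intercept0")
    cols.append(t)
    labels.append("beta")
    for k in range(Xc.shape[1]):
        cols.append(Xc[:, k] * t)
        labels.append(f"beta_x[{k}]")
    cols.append(xt)
    labels.append("mu_Delta")
    return np.column_stack(cols), labels, intercept_used


def _finalize_sigmas(log_rho, sigma2):
    sigma_eps = math.sqrt(sigma2)
    sigma_zeta = math.sqrt(math.exp(np.clip(log_rho[0], -40, 40)) * sigma2)
    sigma_re = math.sqrt(math.exp(np.clip(log_rho[1], -40, 40)) * sigma2)
    boundary = []
    if sigma_zeta < BOUNDARY_SD:
        sigma_zeta = 0.0
        boundary.append("sigma_zeta")
    if sigma_re < BOUNDARY_SD:
        sigma_re = 0.0
        boundary.append("sigma_Delta")
    if sigma_eps < BOUNDARY_SD:
        boundary.append("sigma_eps")
    return sigma_zeta, sigma_re, sigma_eps, boundary


# ---------------------------------------------------------------------------
# public fitting interface
# ---------------------------------------------------------------------------


def fit_model(data: CohortData, spec: ModelSpec, **kwargs) -> ModelFit:
    """Dispatch to the covariable or no-covariable fit per the ModelSpec."""
    if spec.with_covariables:
        return fit_with_covariables(data, spec, **kwargs)
    kwargs.pop("tol", None)
    kwargs.pop("max_iter", None)
    kwargs.pop("init", None)
    return fit_no_covariables(data, spec.lam, **kwargs)


def fit_no_covariables(
    data: CohortData,
    lam: float,
    rho_start=None,
    compute_modes: bool = True,
) -> ModelFit:
    """ML fit of the nested random-intercept model (no covariables).

    z_ijt = mu_theta + beta*t + zeta_j + alpha_i + eps; a single
    unconstrained mixed-model fit (n_iterations = 1). The eye-level SD
    (sigma_theta in the disease-age parameterization) is stored in
    ``sigma_Delta``.
    """
    df = data.df
    y = df["ga_size_mm2"].to_numpy(dtype=float)
    z = boxcox.transform(y, lam)
    t = df["time_years"].to_numpy(dtype=float)
    groups = _Groups(df)
    X = np.column_stack([np.ones_like(t), t])
    u = np.ones_like(t)
    lmm = _ProfiledLMM(groups, X, z, u)
    sol = lmm.fit(rho_start=rho_start)
    coefs = sol["coefs"]
    sigma_zeta, sigma_re, sigma_eps, boundary = _finalize_sigmas(
        sol["log_rho"], sol["sigma2"]
    )
    n_params = 2 + 2 + 1
    loglik_z = sol["loglik"]
    loglik_y = boxcox.loglik_original_scale(loglik_z, lam, y)
    spec = ModelSpec(with_covariables=False, lam=lam)
    xtilde = {key: 1.0 for key in groups.eye_keys}
    fit = ModelFit(
        spec=spec,
        beta=float(coefs[1]),
        beta_x={},
        mu_Delta=None,
        mu_theta=float(coefs[0]),
        intercept0=0.0,
        sigma_Delta=sigma_re,
        sigma_zeta=sigma_zeta,
        sigma_eps=sigma_eps,
        xtilde=xtilde,
        zeta_hat=None,
        gamma_hat=None,
        fitted_z=None,
        residuals=None,
        loglik_z=loglik_z,
        loglik_y=loglik_y,
        aic_y=-2.0 * loglik_y + 2 * n_params,
        n_params=n_params,
        n_iterations=1,
        converged=True,
        boundary=boundary,
    )
    if compute_modes:
        zeta, gamma = lmm.conditional_modes(sol["log_rho"], coefs)
        fit.zeta_hat, fit.gamma_hat = zeta, gamma
        _attach_fitted(fit, data)
    return fit


def fit_with_covariables(
    data: CohortData,
    spec: ModelSpec,
    tol: float = 1e-6,
    max_iter: int = 50,
    init: Mapping[tuple[str, str], float] | np.ndarray | None = None,
    rho_start=None,
    compute_modes: bool = True,
) -> ModelFit:
    """Iterative working-covariable fit of the constrained model.

    Alternates (i) computing the working covariable
    xt_i = beta + beta_x' x_i from the current coefficients with
    (ii) refitting the linear mixed model in which xt_i is a fixed
    regressor (coefficient mu_Delta) and the known loading of both
    random effects, until the maximum relative change of
    (beta, beta_x, mu_Delta) falls below ``tol``. The default start is
    xt_i = 1; ``init`` may supply a per-eye warm start (the fixed
    point does not depend on it).
    """
    if not spec.with_covariables:
        raise ValueError("spec.with_covariables must be True")
    if tol <= 0 or max_iter < 1:
        raise ValueError("tol must be > 0 and max_iter >= 1")
    df = data.df
    missing = [c for c in spec.covariable_names if c not in df.columns]
    if missing:
        raise ValueError(f"cohort lacks covariable column(s): {missing}")
    y = df["ga_size_mm2"].to_numpy(dtype=float)
    z = boxcox.transform(y, spec.lam)
    t = df["time_years"].to_numpy(dtype=float)
    Xc = df[list(spec.covariable_names)].to_numpy(dtype=float)
    groups = _Groups(df)
    k = Xc.shape[1]

    if init is None:
        xt = np.ones_like(t)
    elif isinstance(init, np.ndarray):
        xt = np.asarray(init, dtype=float)  # per-row warm start
    else:
        eye_of_row = list(zip(df["patient_id"], df["eye_id"]))
        xt = np.array([float(init[key]) for key in eye_of_row])

    prev = None
    rho = rho_start
    converged = False
    trace: list[dict[str, float]] = []
    warnings: list[str] = []
    n_it = 0
    for n_it in range(1, max_iter + 1):
        X, labels, _ = _build_design(
            t, Xc, xt, spec.include_stability_intercept
        )
        lmm = _ProfiledLMM(groups, X, z, xt)
        sol = lmm.fit(rho_start=rho)
        rho = sol["log_rho"]
        coefs = dict(zip(labels, sol["coefs"]))
        beta = coefs["beta"]
        beta_x = np.array([coefs[f"beta_x[{i}]"] for i in range(k)])
        mu_Delta = coefs["mu_Delta"]
        trace.append(
            {"beta": beta, **{f"beta_x[{i}]": beta_x[i] for i in range(k)},
             "mu_Delta": mu_Delta, "loglik_z": sol["loglik"]}
        )
        vec = np.concatenate(([beta], beta_x, [mu_Delta]))
        if prev is not None:
            rel = np.max(np.abs(vec - prev) / (np.abs(prev) + 1e-8))
            if rel < tol:
                converged = True
                break
        prev = vec
        xt = beta + Xc @ beta_x

    if not converged and max_iter > 1:
        warnings.append(f"not converged after {n_it} iterations")
    small = np.abs(xt) < 1e-8
    if np.any(small):
        bad = sorted({(p, e) for p, e, s in zip(df["patient_id"], df["eye_id"], small) if s})
        warnings.append(
            f"working covariable ~ 0 for eyes {bad[:10]}: random-effect "
            f"loading vanishes there"
        )

    sigma_zeta, sigma_Delta, sigma_eps, boundary = _finalize_sigmas(
        rho, sol["sigma2"]
    )
    n_fixed = len(labels)
    n_params = n_fixed + 2 + 1
    loglik_z = sol["loglik"]
    loglik_y = boxcox.loglik_original_scale(loglik_z, spec.lam, y)
    eye_of_row = list(zip(df["patient_id"], df["eye_id"]))
    xtilde_map: dict[tuple[str, str], float] = {}
    for key, v in zip(eye_of_row, xt):
        xtilde_map.setdefault(key, float(v))
    fit = ModelFit(
        spec=spec,
        beta=float(beta),
        beta_x={name: float(b) for name, b in zip(spec.covariable_names, beta_x)},
        mu_Delta=float(mu_Delta),
        mu_theta=None,
        intercept0=float(coefs.get("intercept0", 0.0)),
        sigma_Delta=sigma_Delta,
        sigma_zeta=sigma_zeta,
        sigma_eps=sigma_eps,
        xtilde=xtilde_map,
        zeta_hat=None,
        gamma_hat=None,
        fitted_z=None,
        residuals=None,
        loglik_z=loglik_z,
        loglik_y=loglik_y,
        aic_y=-2.0 * loglik_y + 2 * n_params,
        n_params=n_params,
        n_iterations=n_it,
        converged=converged,
        boundary=boundary,
        warnings=warnings,
        coef_trace=trace,
    )
    if compute_modes:
        zeta, gamma = lmm.conditional_modes(rho, sol["coefs"])
        fit.zeta_hat, fit.gamma_hat = zeta, gamma
        _attach_fitted(fit, data)
    return fit


# ---------------------------------------------------------------------------
# brute-force constrained-ML oracle (testing path; small cohorts)
# ---------------------------------------------------------------------------


def _constrained_nll(params, t, z, Xc, groups, include_intercept, k):
    """Exact constrained negative log-likelihood; xt recomputed inside."""
    beta = params[0]
    beta_x = params[1 : 1 + k]
    mu_Delta = params[1 + k]
    s_delta, s_zeta, s_eps = np.exp(np.clip(params[2 + k : 5 + k], -20, 20))
    xt_eye = beta + Xc @ beta_x  # per row (covariables constant within eye)
    base = t * xt_eye + mu_Delta * xt_eye
    n = t.size
    # profile the stability intercept c0 by GLS if requested
    chols = []
    resids = []
    num = den = 0.0
    logdet = 0.0
    for j, rows in enumerate(groups.patient_rows):
        uj = xt_eye[rows]
        V = s_eps**2 * np.eye(rows.size) + s_zeta**2 * np.outer(uj, uj)
        for local in groups.eye_rows[j]:
            V[np.ix_(local, local)] += s_delta**2 * np.outer(uj[local], uj[local])
        try:
            L = np.linalg.cholesky(V)
        except np.linalg.LinAlgError:
            return 1e100
        chols.append((rows, L))
        r = z[rows] - base[rows]
        resids.append(r)
        logdet += 2.0 * float(np.sum(np.log(np.diag(L))))
        if include_intercept:
            Vi_r = np.linalg.solve(L.T, np.linalg.solve(L, r))
            Vi_1 = np.linalg.solve(L.T, np.linalg.solve(L, np.ones(rows.size)))
            num += float(np.sum(Vi_r))
            den += float(np.sum(Vi_1))
    c0 = num / den if (include_intercept and den > 0) else 0.0
    quad = 0.0
    for (rows, L), r in zip(chols, resids):
        rr = r - c0
        w = np.linalg.solve(L, rr)
        quad += float(w @ w)
    return 0.5 * (n * math.log(2.0 * math.pi) + logdet + quad), c0


def _heuristic_start(data: CohortData, spec: ModelSpec) -> np.ndarray:
    """Independent starting point from per-eye OLS lines."""
    df = data.df
    k = len(spec.covariable_names)
    slopes, inters, xrows, resid_sds = [], [], [], []
    for _, g in df.groupby(["patient_id", "eye_id"], sort=False):
        tt = g["time_years"].to_numpy(dtype=float)
        zz = boxcox.transform(g["ga_size_mm2"].to_numpy(dtype=float), spec.lam)
        A = np.column_stack([np.ones_like(tt), tt])
        coef, res, *_ = np.linalg.lstsq(A, zz, rcond=None)
        inters.append(coef[0])
        slopes.append(coef[1])
        if len(tt) > 2 and len(res):
            resid_sds.append(math.sqrt(res[0] / (len(tt) - 2)))
        if k:
            xrows.append(g[list(spec.covariable_names)].iloc[0].to_numpy(dtype=float))
    slopes = np.asarray(slopes)
    inters = np.asarray(inters)
    if k:
        Xe = np.column_stack([np.ones(len(slopes)), np.asarray(xrows)])
        coef, *_ = np.linalg.lstsq(Xe, slopes, rcond=None)
        beta0, bx0 = coef[0], coef[1:]
    else:
        beta0, bx0 = float(np.mean(slopes)), np.zeros(0)
    safe = np.where(np.abs(slopes) > 1e-3, slopes, np.nan)
    ratio = inters / safe
    ratio = ratio[np.isfinite(ratio)]
    mu0 = float(np.median(ratio)) if ratio.size else 1.0
    spread = float(np.std(ratio)) if ratio.size > 1 else 1.0
    s_eps0 = float(np.median(resid_sds)) if resid_sds else 0.3
    s0 = max(spread / math.sqrt(2.0), 0.1)
    return np.concatenate(
        ([beta0], bx0, [mu0], np.log([s0, s0, max(s_eps0, 1e-3)]))
    )


def brute_force_ml(
    data: CohortData,
    spec: ModelSpec,
    start: Sequence[float] | None = None,
) -> ModelFit:
    """Directly maximize the exact constrained marginal likelihood.

    Optimizes (beta, beta_x, mu_Delta, log sigma_Delta, log sigma_zeta,
    log sigma) with the working covariable recomputed from the current
    (beta, beta_x) inside the objective, so the constraint is exact
    rather than iterated. Intended as an independent cross-check on
    small cohorts (guideline: <= 40 eyes); for the no-covariable spec
    it optimizes (mu_theta, beta, log SDs) of the nested
    random-intercept model.
    """
    df = data.df
    y = df["ga_size_mm2"].to_numpy(dtype=float)
    z = boxcox.transform(y, spec.lam)
    t = df["time_years"].to_numpy(dtype=float)
    groups = _Groups(df)
    k = len(spec.covariable_names)

    if spec.with_covariables:
        Xc = df[list(spec.covariable_names)].to_numpy(dtype=float)
        include_intercept = spec.include_stability_intercept

        def nll(p):
            return _constrained_nll(p, t, z, Xc, groups, include_intercept, k)[0]

        if start is not None:
            x0s = [np.asarray(start, dtype=float)]
        else:
            # multi-start: the per-eye-OLS heuristic plus the iterative
            # algorithm's fixed point (a valid likelihood point the exact
            # optimizer must at least match)
            x0s = [_heuristic_start(data, spec)]
            try:
                it = fit_with_covariables(data, spec, compute_modes=False)
                x0s.append(
                    np.concatenate(
                        (
                            [it.beta],
                            [it.beta_x[n_] for n_ in spec.covariable_names],
                            [it.mu_Delta],
                            np.log(
                                np.maximum(
                                    [it.sigma_Delta, it.sigma_zeta, it.sigma_eps],
                                    1e-6,
                                )
                            ),
                        )
                    )
                )
            except FitError:
                pass
    else:
        Xc = np.zeros((t.size, 0))
        include_intercept = False

        def nll(p):
            beta = p[1]
            mu_theta = p[0]
            s_re, s_zeta, s_eps = np.exp(np.clip(p[2:5], -20, 20))
            base = mu_theta + beta * t
            total = 0.0
            for j, rows in enumerate(groups.patient_rows):
                m = rows.size
                V = s_eps**2 * np.eye(m) + s_zeta**2 * np.ones((m, m))
                for local in groups.eye_rows[j]:
                    V[np.ix_(local, local)] += s_re**2
                try:
                    L = np.linalg.cholesky(V)
                except np.linalg.LinAlgError:
                    return 1e100
                w = np.linalg.solve(L, z[rows] - base[rows])
                total += 0.5 * (
                    m * math.log(2.0 * math.pi)
                    + 2.0 * float(np.sum(np.log(np.diag(L))))
                    + float(w @ w)
                )
            return total

        if start is not None:
            x0s = [np.asarray(start, dtype=float)]
        else:
            h = _heuristic_start(data, spec)
            # h = [beta, mu_Delta, log s, log s, log s_eps] for k = 0
            x0s = [np.array([h[1] * h[0], h[0], h[2], h[3], h[4]])]

    best = None
    for x0 in x0s:
        x_cur = x0
        for _ in range(3):  # NM with restarts at the incumbent optimum
            res = optimize.minimize(
                nll,
                x_cur,
                method="Nelder-Mead",
                options={"xatol": 1e-9, "fatol": 1e-11, "maxiter": 20000, "maxfev": 20000},
            )
            if best is None or res.fun < best.fun:
                best = res
            x_cur = res.x
    if best is None or not np.isfinite(best.fun):
        raise FitError(f"brute-force optimization failed: {best}")
    p = best.x
    loglik_z = -float(best.fun)
    loglik_y = boxcox.loglik_original_scale(loglik_z, spec.lam, y)
    eye_of_row = list(zip(df["patient_id"], df["eye_id"]))

    if spec.with_covariables:
        beta = float(p[0])
        beta_x = {n_: float(v) for n_, v in zip(spec.covariable_names, p[1 : 1 + k])}
        mu_Delta = float(p[1 + k])
        s_delta, s_zeta, s_eps = np.exp(np.clip(p[2 + k : 5 + k], -20, 20))
        _, c0 = _constrained_nll(p, t, z, Xc, groups, include_intercept, k)
        xt = beta + Xc @ p[1 : 1 + k]
        n_params = (1 if include_intercept else 0) + 1 + k + 1 + 2 + 1
        xtilde_map: dict[tuple[str, str], float] = {}
        for key, v in zip(eye_of_row, xt):
            xtilde_map.setdefault(key, float(v))
        fit = ModelFit(
            spec=spec,
            beta=beta,
            beta_x=beta_x,
            mu_Delta=mu_Delta,
            mu_theta=None,
            intercept0=float(c0),
            sigma_Delta=float(s_delta),
            sigma_zeta=float(s_zeta),
            sigma_eps=float(s_eps),
            xtilde=xtilde_map,
            zeta_hat=None,
            gamma_hat=None,
            fitted_z=None,
            residuals=None,
            loglik_z=loglik_z,
            loglik_y=loglik_y,
            aic_y=-2.0 * loglik_y + 2 * n_params,
            n_params=n_params,
            n_iterations=1,
            converged=bool(best.success or best.fun < 1e99),
        )
    else:
        mu_theta, beta = float(p[0]), float(p[1])
        s_re, s_zeta, s_eps = np.exp(np.clip(p[2:5], -20, 20))
        n_params = 2 + 2 + 1
        fit = ModelFit(
            spec=spec,
            beta=beta,
            beta_x={},
            mu_Delta=None,
            mu_theta=mu_theta,
            intercept0=0.0,
            sigma_Delta=float(s_re),
            sigma_zeta=float(s_zeta),
            sigma_eps=float(s_eps),
            xtilde={key: 1.0 for key in groups.eye_keys},
            zeta_hat=None,
            gamma_hat=None,
            fitted_z=None,
            residuals=None,
            loglik_z=loglik_z,
            loglik_y=loglik_y,
            aic_y=-2.0 * loglik_y + 2 * n_params,
            n_params=n_params,
            n_iterations=1,
            converged=bool(best.success or best.fun < 1e99),
        )
    zeta, gamma = conditional_modes(fit, data)
    fit.zeta_hat, fit.gamma_hat = zeta, gamma
    _attach_fitted(fit, data)
    return fit


# ---------------------------------------------------------------------------
# conditional modes, fitted values and residuals
# ---------------------------------------------------------------------------


def _fixed_part(fit: ModelFit, data: CohortData) -> np.ndarray:
    """Fixed-effect linear predictor per data row (no random effects)."""
    df = data.df
    t = df["time_years"].to_numpy(dtype=float)
    if fit.spec.with_covariables:
        Xc = df[list(fit.spec.covariable_names)].to_numpy(dtype=float)
        bx = np.array([fit.beta_x[n_] for n_ in fit.spec.covariable_names])
        xt = np.array(
            [fit.xtilde[(p, e)] for p, e in zip(df["patient_id"], df["eye_id"])]
        )
        return fit.intercept0 + fit.beta * t + (Xc @ bx) * t + fit.mu_Delta * xt
    return fit.mu_theta + fit.beta * t


def _loadings(fit: ModelFit, data: CohortData) -> np.ndarray:
    df = data.df
    return np.array(
        [fit.xtilde[(p, e)] for p, e in zip(df["patient_id"], df["eye_id"])]
    )


def conditional_modes(fit: ModelFit, data: CohortData):
    """Empirical-Bayes modes of the random effects at the ML parameters.

    Returns ``(zeta_hat, gamma_hat)``: patient -> mode and eye -> mode.
    Closed-form generalized-least-squares solve per patient block.
    """
    df = data.df
    groups = _Groups(df)
    y = df["ga_size_mm2"].to_numpy(dtype=float)
    z = boxcox.transform(y, fit.spec.lam)
    resid = z - _fixed_part(fit, data)
    u = _loadings(fit, data)
    s_eps2 = max(fit.sigma_eps**2, _SIGMA2_FLOOR)
    rho_z = fit.sigma_zeta**2 / s_eps2
    rho_e = fit.sigma_Delta**2 / s_eps2
    zeta: dict[str, float] = {}
    gamma: dict[tuple[str, str], float] = {}
    for j, rows in enumerate(groups.patient_rows):
        uj = u[rows]
        Lam = np.eye(rows.size) + rho_z * np.outer(uj, uj)
        for local in groups.eye_rows[j]:
            Lam[np.ix_(local, local)] += rho_e * np.outer(uj[local], uj[local])
        try:
            w = np.linalg.solve(Lam, resid[rows])
        except np.linalg.LinAlgError as exc:
            raise FitError(
                f"singular covariance block for patient {groups.patients[j]!r}"
            ) from exc
        zeta[groups.patients[j]] = float(rho_z * (uj @ w))
        for key, local in zip(groups.patient_eyes[j], groups.eye_rows[j]):
            gamma[key] = float(rho_e * (uj[local] @ w[local]))
    return zeta, gamma


def _attach_fitted(fit: ModelFit, data: CohortData) -> None:
    """Store per-row fitted z (including random effects) and residuals."""
    df = data.df
    z = boxcox.transform(df["ga_size_mm2"].to_numpy(dtype=float), fit.spec.lam)
    u = _loadings(fit, data)
    re = np.array(
        [
            fit.zeta_hat[p] + fit.gamma_hat[(p, e)]
            for p, e in zip(df["patient_id"], df["eye_id"])
        ]
    )
    fit.fitted_z = _fixed_part(fit, data) + u * re
    fit.residuals = z - fit.fitted_z


def linear_predictor(
    fit: ModelFit,
    data: CohortData,
    eye_keys: Sequence[tuple[str, str]],
    ts: Sequence[float],
    include_random: bool = True,
) -> np.ndarray:
    """Predicted transformed size for arbitrary (eye, t) targets.

    Uses the fit's conditional modes for the random effects of known
    eyes/patients when ``include_random`` is set.
    """
    eye_tab = data.eye_table().set_index(["patient_id", "eye_id"])
    out = np.empty(len(eye_keys))
    for i, ((pid, eid), tv) in enumerate(zip(eye_keys, ts)):
        if fit.spec.with_covariables:
            x = eye_tab.loc[(pid, eid), list(fit.spec.covariable_names)].to_numpy(
                dtype=float
            )
            bx = np.array([fit.beta_x[n_] for n_ in fit.spec.covariable_names])
            xt = fit.xtilde[(pid, eid)]
            val = fit.intercept0 + fit.beta * tv + float(x @ bx) * tv + fit.mu_Delta * xt
            if include_random:
                val += xt * (fit.zeta_hat[pid] + fit.gamma_hat[(pid, eid)])
        else:
            val = fit.mu_theta + fit.beta * tv
            if include_random:
                val += fit.zeta_hat[pid] + fit.gamma_hat[(pid, eid)]
        out[i] = val
    return out


def residual_diagnostics(fit: ModelFit, data: CohortData) -> pd.DataFrame:
    """Per-row table of fitted values (including random effects) and residuals.

    This is the exact input for residual-vs-fitted and QQ diagnostics,
    and the single source of the smearing residual pool used by the
    prediction module.
    """
    if fit.fitted_z is None:
        zeta, gamma = conditional_modes(fit, data)
        fit.zeta_hat, fit.gamma_hat = zeta, gamma
        _attach_fitted(fit, data)
    df = data.df
    return pd.DataFrame(
        {
            "patient_id": df["patient_id"],
            "eye_id": df["eye_id"],
            "time_years": df["time_years"],
            "fitted_z": fit.fitted_z,
            "residual": fit.residuals,
        }
    )


# ---------------------------------------------------------------------------
# fit summaries
# ---------------------------------------------------------------------------


def fit_summary_dict(fit: ModelFit) -> dict:
    """Machine-readable fit report (coefficients, variances, likelihoods)."""
    return {
        "model": "with_covariables" if fit.spec.with_covariables else "no_covariables",
        "lambda": fit.spec.lam,
        "coefficients": {
            **({"mu_theta": fit.mu_theta} if fit.mu_theta is not None else {}),
            **({"mu_Delta": fit.mu_Delta} if fit.mu_Delta is not None else {}),
            "beta": fit.beta,
            **{f"beta_x:{n_}": v for n_, v in fit.beta_x.items()},
            "intercept0": fit.intercept0,
        },
        "variance_components": {
            "sigma_Delta": fit.sigma_Delta,
            "sigma_Delta^2": fit.sigma_Delta**2,
            "sigma_zeta": fit.sigma_zeta,
            "sigma_zeta^2": fit.sigma_zeta**2,
            "sigma_eps": fit.sigma_eps,
            "sigma_eps^2": fit.sigma_eps**2,
        },
        "loglik_z": fit.loglik_z,
        "loglik_y": fit.loglik_y,
        "aic_y": fit.aic_y,
        "n_params": fit.n_params,
        "n_iterations": fit.n_iterations,
        "converged": fit.converged,
        "boundary": fit.boundary,
        "warnings": fit.warnings,
    }


def fit_summary_text(fit: ModelFit) -> str:
    d = fit_summary_dict(fit)
    lines = [
        f"Model ({d['model']}), Box-Cox lambda = {d['lambda']:g}",
        "Coefficients:",
    ]
    for k_, v in d["coefficients"].items():
        lines.append(f"  {k_:24s} {v: .4f}")
    lines.append("Variance components (SD / variance):")
    vc = d["variance_components"]
    for nm in ("sigma_Delta", "sigma_zeta", "sigma_eps"):
        lines.append(f"  {nm:24s} {vc[nm]: .4f}  ({vc[nm]**2:.4f})")
    lines.append(
        f"logLik(z) = {d['loglik_z']:.3f}   logLik(y) = {d['loglik_y']:.3f}   "
        f"AIC(y) = {d['aic_y']:.2f}"
    )
    lines.append(
        f"iterations = {d['n_iterations']}, converged = {d['converged']}"
    )
    return "\n".join(lines)


def write_fit_summary(fit: ModelFit, json_path=None, text_path=None) -> None:
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(fit_summary_dict(fit), fh, indent=2)
    if text_path is not None:
        with open(text_path, "w") as fh:
            fh.write(fit_summary_text(fit) + "\n")
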