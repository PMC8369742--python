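"""Cluster-bootstrap confidence intervals for the fixed effects.

Residuals of the fitted trajectory model are typically not Gaussian
even after transformation, so Wald-type intervals based on asymptotic
normality are avoided. Instead, whole patients (the outermost
exchangeable unit, carrying all their eyes and visits) are resampled
with replacement, the model is refitted at the fixed, pre-selected
lambda, and percentile intervals are formed over the replicate
estimates.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .constrained_lmm import ModelFit, ModelSpec, fit_model
from .data_model import CohortData

__all__ = ["BootstrapResult", "bootstrap_ci"]


@dataclass
class BootstrapResult:
    """Percentile bootstrap CIs for the fixed-effect coefficients."""

    names: list[str]
    point: dict[str, float]  # full-data estimates
    ci_lower: dict[str, float]
    ci_upper: dict[str, float]
    B: int
    level: float
    n_failed: int
    replicate_estimates: pd.DataFrame  # one row per successful replicate

    def to_frame(self) -> pd.DataFrame:
        """Risk-factor-table style export: variable, estimate, CI bounds."""
        return pd.DataFrame(
            {
                "variable": self.names,
                "estimate": [self.point[n] for n in self.names],
                "ci_lower": [self.ci_lower[n] for n in self.names],
                "ci_upper": [self.ci_upper[n] for n in self.names],
            }
        )

    def to_text(self) -> str:
        lines = [f"{self.level:.0%} percentile bootstrap CIs "
                 f"(B = {self.B}, {self.n_failed} failed replicates)"]
        for n in self.names:
            lines.append(
                f"  {n:28s} {self.point[n]: .4f}  "
                f"({self.ci_lower[n]: .4f}, {self.ci_upper[n]: .4f})"
            )
        return "\n".join(lines)


def _coef_vector(fit: ModelFit) -> dict[str, float]:
    out: dict[str, float] = {"beta": fit.beta}
    for n, v in fit.beta_x.items():
        out[f"beta_x:{n}"] = v
    if fit.mu_Delta is not None:
        out["mu_Delta"] = fit.mu_Delta
    if fit.mu_theta is not None:
        out["mu_theta"] = fit.mu_theta
    return out


def _resample_patients(
    data: CohortData,
    rng: np.random.Generator,
    rows_by_patient: list[np.ndarray] | None = None,
) -> CohortData:
    """Patient-cluster resample; duplicated patients get fresh identifiers."""
    pids = data.patient_ids
    if rows_by_patient is None:
        idx = {p: [] for p in pids}
        for r, p in enumerate(data.df["patient_id"]):
            idx[p].append(r)
        rows_by_patient = [np.asarray(idx[p]) for p in pids]
    picks = rng.integers(0, len(pids), size=len(pids))
    take = np.concatenate([rows_by_patient[i] for i in picks])
    df = data.df.iloc[take].copy()
    df["patient_id"] = np.repeat(
        [f"{pids[i]}#bs{b}" for b, i in enumerate(picks)],
        [rows_by_patient[i].size for i in picks],
    )
    # clusters are intact copies of validated patients: skip re-validation
    return CohortData(df, list(data.covariable_names), validate=False)


def bootstrap_ci(
    data: CohortData,
    spec: ModelSpec,
    B: int = 1000,
    seed: int | None = None,
    level: float = 0.95,
    fit_settings: dict | None = None,
    max_failure_fraction: float = 0.10,
) -> BootstrapResult:
    """Patient-cluster percentile bootstrap for the fixed effects.

    Lambda stays fixed at the ModelSpec's value across replicates
    (re-selecting it per replicate would change the estimand). Refits
    are warm-started from the full-data working covariables; the
    algorithm's fixed point does not depend on its start. Replicate
    fit failures are counted; more than ``max_failure_fraction`` of B
    failing raises an error.
    """
    if B < 1:
        raise ValueError("B must be >= 1")
    rng = np.random.default_rng(seed)
    settings = dict(fit_settings or {})
    full = fit_model(data, spec, compute_modes=False, **settings)
    point = _coef_vector(full)
    names = list(point)

    rho_start = None
    if full.sigma_eps > 0:
        rho_start = (
            np.log(max(full.sigma_zeta / full.sigma_eps, 1e-8) ** 2),
            np.log(max(full.sigma_Delta / full.sigma_eps, 1e-8) ** 2),
        )

    pids = data.patient_ids
    idx: dict[str, list[int]] = {p: [] for p in pids}
    for r_, p_ in enumerate(data.df["patient_id"]):
        idx[p_].append(r_)
    rows_by_patient = [np.asarray(idx[p]) for p in pids]

    rows = []
    n_failed = 0
    for _ in range(B):
        boot = _resample_patients(data, rng, rows_by_patient)
        try:
            if spec.with_covariables:
                bx = np.array([full.beta_x[n] for n in spec.covariable_names])
                Xc = boot.df[list(spec.covariable_names)].to_numpy(dtype=float)
                init = full.beta + Xc @ bx
                fit = fit_model(
                    boot,
                    spec,
                    init=init,
                    rho_start=rho_start,
                    compute_modes=False,
                    **settings,
                )
            else:
                fit = fit_model(
                    boot, spec, rho_start=rho_start, compute_modes=False, **settings
                )
            rows.append(_coef_vector(fit))
        except Exception:  # noqa: BLE001 - counted
            n_failed += 1
    if n_failed > max_failure_fraction * B:
        raise RuntimeError(
            f"{n_failed}/{B} bootstrap replicates failed to fit; the model "
            f"is too fragile for this data"
        )
    reps = pd.DataFrame(rows)
    alpha = 1.0 - level
    lo = reps.quantile(alpha / 2)
    hi = reps.quantile(1 - alpha / 2)
    return BootstrapResult(
        names=names,
        point=point,
        ci_lower={n: float(lo[n]) for n in names},
        ci_upper={n: float(hi[n]) for n in names},
        B=B,
        level=level,
        n_failed=n_failed,
        replicate_estimates=reps,
    )
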