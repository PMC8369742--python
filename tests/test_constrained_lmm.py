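"""Constrained mixed-model fitting: exact cases, recovery, oracle checks."""

import numpy as np
import pandas as pd
import pytest

import gaprog
from gaprog.constrained_lmm import fit_summary_dict, fit_summary_text

from conftest import linear_cohort, toy_cohort_df


def _zscale_cohort(rng, n_patients, mu_theta, beta, s_zeta, s_theta, s_eps,
                   lam=1.0, times=(0.0, 1.0, 2.0, 3.0)):
    """Nested random-intercept data generated directly on the z scale.

    The intercept is placed high enough that all sizes stay positive on
    the original scale.
    """
    rows = []
    for j in range(n_patients):
        zeta = rng.normal(0, s_zeta)
        n_eyes = 2 if rng.random() < 0.5 else 1
        for e in range(n_eyes):
            alpha = rng.normal(0, s_theta)
            for t in times:
                z = mu_theta + beta * t + zeta + alpha + rng.normal(0, s_eps)
                rows.append(
                    {
                        "patient_id": f"P{j}",
                        "eye_id": ("OD", "OS")[e],
                        "time_years": t,
                        "ga_size_mm2": gaprog.inverse_transform(z, lam),
                        "age_at_baseline_years": 75.0,
                    }
                )
    return gaprog.CohortData(pd.DataFrame(rows))


def test_exact_linear_single_eye():
    """Noise-free z = 2 + 0.5 t at lambda = 1 is recovered exactly."""
    data = linear_cohort(n_patients=1, mu_theta=2.0, beta=0.5, lam=1.0,
                         times=(0.0, 1.0, 2.0))
    fit = gaprog.fit_no_covariables(data, 1.0)
    assert fit.beta == pytest.approx(0.5, abs=1e-8)
    assert fit.mu_theta == pytest.approx(2.0, abs=1e-8)
    assert fit.sigma_eps < 1e-5


def test_no_covariable_recovery():
    """ML recovers the nested-model parameters within 3 MC SEs (z scale)."""
    truth = dict(mu_theta=20.0, beta=0.42, s_zeta=4.03, s_theta=1.83, s_eps=0.42)
    rng = np.random.default_rng(42)
    ests = []
    for _ in range(8):
        data = _zscale_cohort(rng, 100, **truth)
        fit = gaprog.fit_no_covariables(data, 1.0, compute_modes=False)
        ests.append([fit.mu_theta, fit.beta, fit.sigma_zeta, fit.sigma_Delta,
                     fit.sigma_eps])
    ests = np.asarray(ests)
    means = ests.mean(axis=0)
    ses = ests.std(axis=0, ddof=1) / np.sqrt(len(ests))
    targets = [truth["mu_theta"], truth["beta"], truth["s_zeta"],
               truth["s_theta"], truth["s_eps"]]
    for m, se, tgt in zip(means, ses, targets):
        assert abs(m - tgt) < 3 * max(se, 1e-3), (m, se, tgt)


def test_brute_force_matches_profiled_no_covariables(small_cohorts):
    """Same model, two optimizers: logliks agree to 1e-5."""
    _, data = small_cohorts[0]
    spec = gaprog.ModelSpec(with_covariables=False, lam=0.45)
    f1 = gaprog.fit_no_covariables(data, 0.45)
    f2 = gaprog.brute_force_ml(data, spec)
    assert f2.loglik_z == pytest.approx(f1.loglik_z, abs=1e-5)
    assert f2.beta == pytest.approx(f1.beta, rel=1e-4)


def test_oracle_dominance(small_cohorts):
    """The exact constrained-ML oracle never falls below the iterative fit.

    The iterative working-covariable fixed point maximizes the
    likelihood only holding the working covariable fixed, so the exact
    optimizer must attain at least the same constrained likelihood.
    """
    for cfg, data in small_cohorts[:6]:
        spec = gaprog.ModelSpec(
            with_covariables=True, covariable_names=cfg.covariable_names, lam=0.45
        )
        it = gaprog.fit_with_covariables(data, spec)
        bf = gaprog.brute_force_ml(data, spec)
        assert bf.loglik_z >= it.loglik_z - 1e-4, (bf.loglik_z, it.loglik_z)


def test_nesting_consistency():
    """With all covariables at 0 the covariable fit reduces to the
    no-covariable fit via mu_theta = beta * mu_Delta."""
    cfg = gaprog.SyntheticConfig(
        seed=88,
        n_patients=60,
        beta_x={"a": 0.0, "b": 0.0},
        covariable_prevalences={"a": 0.5, "b": 0.5},
    )
    data, _, _ = gaprog.generate(cfg)
    df = data.df.copy()
    df[["a", "b"]] = 0.0
    data0 = gaprog.CohortData(df, ["a", "b"])
    spec = gaprog.ModelSpec(with_covariables=True, covariable_names=["a", "b"],
                            lam=0.45)
    fc = gaprog.fit_with_covariables(data0, spec)
    fn = gaprog.fit_no_covariables(data0, 0.45)
    assert fc.beta == pytest.approx(fn.beta, rel=1e-4)
    assert fc.beta * fc.mu_Delta == pytest.approx(fn.mu_theta, rel=1e-3)
    assert fc.loglik_z == pytest.approx(fn.loglik_z, abs=1e-4)


def test_fixed_point_property(fam_fit, fam_cohort, fam_spec):
    """One extra iteration at convergence moves the coefficients < tol."""
    data, _, _ = fam_cohort
    fit = fam_fit
    assert fit.converged
    xt = np.array(
        [
            fit.beta
            + sum(
                fit.beta_x[n] * v
                for n, v in zip(
                    fam_spec.covariable_names,
                    data.df.loc[i, fam_spec.covariable_names],
                )
            )
            for i in data.df.index
        ]
    )
    refit = gaprog.fit_with_covariables(
        data, fam_spec, max_iter=1, init=xt, compute_modes=False
    )
    for a, b in [
        (refit.beta, fit.beta),
        (refit.mu_Delta, fit.mu_Delta),
        *[(refit.beta_x[n], fit.beta_x[n]) for n in fit.beta_x],
    ]:
        assert abs(a - b) / (abs(b) + 1e-8) < 5e-6


def test_convergence_under_20_iterations(fam_fit):
    assert fam_fit.converged
    assert fam_fit.n_iterations < 20


def test_relabeling_and_permutation_invariance(small_cohorts):
    cfg, data = small_cohorts[1]
    spec = gaprog.ModelSpec(
        with_covariables=True, covariable_names=cfg.covariable_names, lam=0.45
    )
    base = gaprog.fit_with_covariables(data, spec, compute_modes=False)
    df = data.df.copy()
    rng = np.random.default_rng(0)
    df = df.iloc[rng.permutation(len(df))].reset_index(drop=True)
    df["patient_id"] = "Q_" + df["patient_id"]
    df["eye_id"] = df["eye_id"].map({"OD": "right", "OS": "left"})
    shuf = gaprog.CohortData(df, list(data.covariable_names))
    refit = gaprog.fit_with_covariables(shuf, spec, compute_modes=False)
    assert refit.beta == pytest.approx(base.beta, rel=1e-5)
    assert refit.mu_Delta == pytest.approx(base.mu_Delta, rel=1e-5)
    assert refit.sigma_zeta == pytest.approx(base.sigma_zeta, rel=1e-4)
    assert refit.loglik_z == pytest.approx(base.loglik_z, abs=1e-6)


def test_conditional_modes_degenerate_prior():
    """With sigma_Delta = sigma_zeta = 0 every mode is exactly 0."""
    data = linear_cohort(n_patients=3)
    fit = gaprog.fit_no_covariables(data, 1.0)
    fit.sigma_Delta = 0.0
    fit.sigma_zeta = 0.0
    fit.sigma_eps = 0.5
    zeta, gamma = gaprog.conditional_modes(fit, data)
    assert all(v == 0.0 for v in zeta.values())
    assert all(v == 0.0 for v in gamma.values())


def test_conditional_mode_limit_is_mean_offset():
    """Single patient, huge sigma_zeta, tiny sigma: zeta_hat -> mean residual."""
    df = toy_cohort_df(n_eyes=1)
    df["ga_size_mm2"] = [2.0, 2.5]  # z = y - 1 at lambda 1
    data = gaprog.CohortData(df)
    fit = gaprog.fit_no_covariables(data, 1.0)
    fit.mu_theta, fit.beta = 0.0, 0.0
    fit.sigma_zeta, fit.sigma_Delta, fit.sigma_eps = 1e4, 0.0, 0.1
    zeta, _ = gaprog.conditional_modes(fit, data)
    # residuals are z = (1.0, 1.5); mean offset 1.25
    assert zeta["P1"] == pytest.approx(1.25, rel=1e-4)


def test_residuals_zero_on_noiseless_data():
    data = linear_cohort(n_patients=4)
    fit = gaprog.fit_no_covariables(data, 1.0)
    tab = gaprog.residual_diagnostics(fit, data)
    assert np.max(np.abs(tab["residual"])) < 1e-6
    assert list(tab.columns) == [
        "patient_id", "eye_id", "time_years", "fitted_z", "residual"
    ]


def test_residuals_single_source_of_truth(fam_fit, fam_cohort):
    """The diagnostics table and the stored residual vector coincide."""
    data, _, _ = fam_cohort
    tab = gaprog.residual_diagnostics(fam_fit, data)
    np.testing.assert_allclose(tab["residual"].to_numpy(), fam_fit.residuals)


def test_stability_intercept_flag_reported(fam_cohort, fam_spec):
    """With the optional fixed intercept on, the coefficient is reported
    and the likelihood can only improve."""
    data, _, _ = fam_cohort
    spec_on = gaprog.ModelSpec(
        with_covariables=True,
        covariable_names=list(fam_spec.covariable_names),
        lam=0.45,
        include_stability_intercept=True,
    )
    f_on = gaprog.fit_with_covariables(data, spec_on, compute_modes=False)
    f_off = gaprog.fit_with_covariables(data, fam_spec, compute_modes=False)
    assert f_on.n_params == f_off.n_params + 1
    assert np.isfinite(f_on.intercept0)
    assert f_on.loglik_z >= f_off.loglik_z - 1e-4


def test_fit_summary_exports(fam_fit):
    d = fit_summary_dict(fam_fit)
    assert d["coefficients"]["beta"] == fam_fit.beta
    assert d["variance_components"]["sigma_zeta^2"] == pytest.approx(
        fam_fit.sigma_zeta**2
    )
    text = fit_summary_text(fam_fit)
    assert "mu_Delta" in text and "AIC" in text


def test_recovery_of_generative_parameters():
    """Mean estimates across replicates sit within 3 MC SEs of truth."""
    reps = []
    for s in range(12):
        cfg = gaprog.SyntheticConfig(seed=6100 + s)
        data, _, _ = gaprog.generate(cfg)
        spec = gaprog.ModelSpec(
            with_covariables=True, covariable_names=cfg.covariable_names, lam=0.45
        )
        fit = gaprog.fit_with_covariables(data, spec, compute_modes=False)
        reps.append(
            [
                fit.beta,
                fit.beta_x["hypercholesterolemia_no"],
                fit.beta_x["hypertension_no"],
                fit.mu_Delta,
            ]
        )
    reps = np.asarray(reps)
    truth = [0.42, 0.11, -0.09, 4.74]
    means = reps.mean(axis=0)
    ses = reps.std(axis=0, ddof=1) / np.sqrt(len(reps))
    for m, se, tgt in zip(means, ses, truth):
        assert abs(m - tgt) < 3 * max(se, 1e-4), (m, se, tgt)
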