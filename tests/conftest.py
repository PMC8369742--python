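"""Shared fixtures: deterministic toy cohorts and seeded synthetic cohorts."""

import numpy as np
import pandas as pd
import pytest

import gaprog


def toy_cohort_df(n_eyes: int = 2) -> pd.DataFrame:
    """Minimal well-formed table: eyes with t = (0, 1), y = (1, 2)."""
    rows = []
    for i in range(n_eyes):
        for t, y in ((0.0, 1.0), (1.0, 2.0)):
            rows.append(
                {
                    "patient_id": f"P{i + 1}",
                    "eye_id": "OD",
                    "time_years": t,
                    "ga_size_mm2": y,
                    "age_at_baseline_years": 75.0,
                }
            )
    return pd.DataFrame(rows)


def linear_cohort(
    n_patients: int = 6,
    mu_theta: float = 2.0,
    beta: float = 0.5,
    lam: float = 1.0,
    times=(0.0, 1.0, 2.0, 3.0),
) -> gaprog.CohortData:
    """Noise-free cohort whose transformed size is exactly mu_theta + beta*t."""
    rows = []
    for i in range(n_patients):
        for t in times:
            z = mu_theta + beta * t
            rows.append(
                {
                    "patient_id": f"P{i + 1}",
                    "eye_id": "OD",
                    "time_years": t,
                    "ga_size_mm2": gaprog.inverse_transform(z, lam),
                    "age_at_baseline_years": 70.0 + i,
                }
            )
    return gaprog.CohortData(pd.DataFrame(rows))


@pytest.fixture(scope="session")
def fam_cohort():
    """One FAM-like synthetic cohort at the default generative settings."""
    data, truth, report = gaprog.generate(gaprog.SyntheticConfig(seed=20260927))
    return data, truth, report


@pytest.fixture(scope="session")
def fam_spec():
    cfg = gaprog.SyntheticConfig()
    return gaprog.ModelSpec(
        with_covariables=True,
        covariable_names=cfg.covariable_names,
        lam=cfg.true_lambda,
    )


@pytest.fixture(scope="session")
def fam_fit(fam_cohort, fam_spec):
    data, _, _ = fam_cohort
    return gaprog.fit_with_covariables(data, fam_spec)


@pytest.fixture(scope="session")
def small_cohorts():
    """Ten small (<= 40 eyes) seeded cohorts for oracle comparisons."""
    out = []
    for s in range(10):
        cfg = gaprog.SyntheticConfig(seed=7000 + s, n_patients=14)
        data, _, _ = gaprog.generate(cfg)
        out.append((cfg, data))
    return out
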