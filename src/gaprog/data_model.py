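"""Longitudinal eye-level data structures and I/O.

The analysis data are long-format tables with one row per eye-visit:
a patient identifier, an eye identifier (unique within patient, e.g.
OD/OS), the time since that eye's baseline visit in years, the
geographic-atrophy (GA) lesion size in mm^2 (strictly positive, as
required by the Box-Cox transformation), the patient's age at the
eye's baseline visit, and optionally per-eye numeric covariables
(binary risk factors coded 0/1, replicated from the patient level).
"""

from __future__ import annotations

from dataclasses import InitVar, dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

#: Mandatory columns of the delimited cohort table, in canonical order.
REQUIRED_COLUMNS = (
    "patient_id",
    "eye_id",
    "time_years",
    "ga_size_mm2",
    "age_at_baseline_years",
)


class CohortFormatError(ValueError):
    """The input table does not have the expected columns/types."""


class CohortValidationError(ValueError):
    """The table parses but violates a model precondition.

    The message names the offending rows (0-based positions within the
    table) so the violation can be audited upstream.
    """


@dataclass(frozen=True)
class VisitRecord:
    """A single eye-visit observation."""

    patient_id: str
    eye_id: str
    t: float  # years since the eye's baseline visit, t = 0 at baseline
    y: float  # GA size in mm^2, strictly positive
    age_at_baseline: float  # patient age at the eye's baseline, years


@dataclass
class CohortData:
    """A validated longitudinal cohort.

    Parameters
    ----------
    df : pandas.DataFrame
        Long-format table with the mandatory columns plus one numeric
        column per covariable. Covariables are time-constant within an
        eye (patient-level factors replicated to both eyes).
    covariable_names : list of str
        Ordered names of the covariable columns (may be empty).
    """

    df: pd.DataFrame
    covariable_names: list[str] = field(default_factory=list)
    #: skip validation for internally constructed cohorts (e.g. cluster
    #: resamples of an already-validated cohort)
    validate: InitVar[bool] = True

    def __post_init__(self, validate: bool = True) -> None:
        self.df = self.df.reset_index(drop=True)
        if validate:
            validate_cohort(self.df, self.covariable_names)

    # -- convenience accessors -------------------------------------------

    @property
    def n_records(self) -> int:
        return len(self.df)

    @property
    def eye_keys(self) -> list[tuple[str, str]]:
        """Unique (patient_id, eye_id) pairs in order of first appearance."""
        seen: dict[tuple[str, str], None] = {}
        for p, e in zip(self.df["patient_id"], self.df["eye_id"]):
            seen.setdefault((p, e), None)
        return list(seen)

    @property
    def n_eyes(self) -> int:
        return len(self.eye_keys)

    @property
    def patient_ids(self) -> list[str]:
        seen: dict[str, None] = {}
        for p in self.df["patient_id"]:
            seen.setdefault(p, None)
        return list(seen)

    @property
    def n_patients(self) -> int:
        return len(self.patient_ids)

    def eye_table(self) -> pd.DataFrame:
        """One row per eye: identifiers, baseline age and covariables."""
        cols = ["patient_id", "eye_id", "age_at_baseline_years"] + list(
            self.covariable_names
        )
        return (
            self.df[cols]
            .groupby(["patient_id", "eye_id"], sort=False)
            .first()
            .reset_index()
        )

    def records(self) -> list[VisitRecord]:
        return [
            VisitRecord(
                patient_id=r.patient_id,
                eye_id=r.eye_id,
                t=float(r.time_years),
                y=float(r.ga_size_mm2),
                age_at_baseline=float(r.age_at_baseline_years),
            )
            for r in self.df.itertuples(index=False)
        ]

    def subset_rows(self, mask: np.ndarray) -> "CohortData":
        """New cohort from a boolean row mask (re-validated)."""
        return CohortData(self.df.loc[mask].copy(), list(self.covariable_names))


def _fmt_rows(rows: Sequence[int], limit: int = 20) -> str:
    rows = list(rows)
    shown = ", ".join(str(r) for r in rows[:limit])
    if len(rows) > limit:
        shown += f", ... ({len(rows)} rows total)"
    return shown


def validate_cohort(df: pd.DataFrame, covariable_names: Sequence[str]) -> None:
    """Check every model precondition; raise on the first class of violation.

    Checks, in order: required columns present; numeric columns numeric and
    finite; y > 0; t >= 0 with a t = 0 baseline row per eye and distinct t
    within eye; >= 2 visits per eye; covariables present, non-missing and
    constant within eye; baseline age constant within eye.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(f"missing mandatory column(s): {missing}")
    missing_cov = [c for c in covariable_names if c not in df.columns]
    if missing_cov:
        raise CohortFormatError(f"missing covariable column(s): {missing_cov}")

    num_cols = ["time_years", "ga_size_mm2", "age_at_baseline_years"] + list(
        covariable_names
    )
    for c in num_cols:
        vals = pd.to_numeric(df[c], errors="coerce")
        bad = np.flatnonzero(vals.isna().to_numpy())
        if bad.size:
            raise CohortValidationError(
                f"column {c!r} has missing/non-numeric values in rows: "
                f"{_fmt_rows(bad)}"
            )

    y = df["ga_size_mm2"].to_numpy(dtype=float)
    bad = np.flatnonzero(~(y > 0) | ~np.isfinite(y))
    if bad.size:
        raise CohortValidationError(
            f"ga_size_mm2 must be strictly positive (Box-Cox domain); "
            f"violated in rows: {_fmt_rows(bad)}"
        )

    t = df["time_years"].to_numpy(dtype=float)
    bad = np.flatnonzero(t < 0)
    if bad.size:
        raise CohortValidationError(
            f"time_years must be >= 0; violated in rows: {_fmt_rows(bad)}"
        )

    grouped = df.groupby(["patient_id", "eye_id"], sort=False)
    dup_rows: list[int] = []
    no_baseline: list[str] = []
    too_few: list[str] = []
    for (pid, eid), g in grouped:
        tt = g["time_years"].to_numpy(dtype=float)
        if len(g) < 2:
            too_few.append(f"{pid}/{eid}")
        if np.unique(tt).size != tt.size:
            dup = g.index[pd.Series(tt).duplicated(keep=False).to_numpy()]
            dup_rows.extend(int(i) for i in dup)
        if not np.any(tt == 0.0):
            no_baseline.append(f"{pid}/{eid}")
    if dup_rows:
        raise CohortValidationError(
            f"duplicate (eye, time) observations in rows: {_fmt_rows(dup_rows)}"
        )
    if no_baseline:
        raise CohortValidationError(
            f"eyes without a t = 0 baseline record: {no_baseline[:20]}"
        )
    if too_few:
        raise CohortValidationError(
            f"eyes with fewer than 2 visits (study inclusion criterion): "
            f"{too_few[:20]}"
        )

    # time-constant per-eye values
    for c in ["age_at_baseline_years"] + list(covariable_names):
        nun = grouped[c].nunique()
        bad_eyes = nun[nun > 1]
        if len(bad_eyes):
            raise CohortValidationError(
                f"column {c!r} must be constant within an eye; varies for "
                f"eyes: {list(bad_eyes.index[:20])}"
            )


def read_cohort(path: str | Path, covariable_names: Sequence[str] = ()) -> CohortData:
    """Read a comma-separated cohort table and validate it.

    The header must contain the five mandatory columns plus one column per
    requested covariable. Covariable coding is taken as-is (binaries are
    expected to be 0/1-coded by the caller).
    """
    try:
        df = pd.read_csv(path)
    except pd.errors.ParserError as exc:  # pragma: no cover - pandas detail
        raise CohortFormatError(f"cannot parse {path}: {exc}") from exc
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise CohortFormatError(
            f"{path}: missing mandatory column(s): {missing}; found "
            f"{list(df.columns)}"
        )
    df["patient_id"] = df["patient_id"].astype(str)
    df["eye_id"] = df["eye_id"].astype(str)
    for c in covariable_names:
        if c in df.columns:
            df[c] = df[c].astype(float)
    keep = list(REQUIRED_COLUMNS) + [c for c in covariable_names]
    missing_cov = [c for c in covariable_names if c not in df.columns]
    if missing_cov:
        raise CohortFormatError(
            f"{path}: missing covariable column(s): {missing_cov}"
        )
    return CohortData(df[keep].copy(), list(covariable_names))


def write_cohort(data: CohortData, path: str | Path) -> None:
    """Write the cohort in the same comma-separated format `read_cohort` reads.

    Floats are written with enough digits that read(write(x)) == x.
    """
    cols = list(REQUIRED_COLUMNS) + list(data.covariable_names)
    data.df[cols].to_csv(path, index=False, float_format="%.15g")
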