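"""Subject-level cohort table for a memory-clinic biomarker study.

A cohort is one row per subject: demographics (age, sex, education, MMSE,
ApoE e4 carriage, clinical diagnosis MCI/dementia), CSF biomarkers (Abeta42,
Abeta40, total tau, pTau181) and plasma biomarkers (Abeta42, Abeta40,
pTau181, pTau217, NfL), all concentrations in pg/ml.  The amyloid reference
label (A+/A-) is defined by a CSF measure against a fixed assay cut-off:
by default the CSF Abeta42/40 ratio at 0.069, with values on the *normal*
side (strictly above) labelled A-.  Tau status (T+/T-) uses CSF pTau181 at
56.5 pg/ml, abnormal at or above the cut-off.

Derived ratio columns (csf_ab42_40, csf_ab42_ttau, csf_ab42_ptau,
plasma_ab42_40) are always recomputed from the raw concentrations; ratio
columns present in an input file are ignored.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "AMYLOID_RATIO_CUTOFF",
    "CSF_PTAU181_CUTOFF",
    "CSF_AB42_PTAU_CUTOFF",
    "BIOMARKER_COLUMNS",
    "DERIVED_RATIOS",
    "CSF_MARKERS",
    "PLASMA_MARKERS",
    "CohortValidationError",
    "ReferenceStandard",
    "CSF_AB42_40_STANDARD",
    "CSF_AB42_PTAU_STANDARD",
    "ATProfile",
    "CohortTable",
    "read_cohort",
    "classify_amyloid",
    "classify_at",
    "label_cohort",
]

# Assay cut-offs (normal ranges are defined by strict inequalities, so a
# value exactly at the cut-off is classified abnormal).
AMYLOID_RATIO_CUTOFF = 0.069   # CSF Abeta42/40, normal above
CSF_PTAU181_CUTOFF = 56.5      # pg/ml, normal below
CSF_AB42_PTAU_CUTOFF = 8.1     # CSF Abeta42/pTau181, normal above

BIOMARKER_COLUMNS = [
    "csf_ab42", "csf_ab40", "csf_ttau", "csf_ptau181",
    "plasma_ab42", "plasma_ab40", "plasma_ptau181", "plasma_ptau217",
    "plasma_nfl",
]

#: derived ratio column -> (numerator, denominator)
DERIVED_RATIOS = {
    "csf_ab42_40": ("csf_ab42", "csf_ab40"),
    "csf_ab42_ttau": ("csf_ab42", "csf_ttau"),
    "csf_ab42_ptau": ("csf_ab42", "csf_ptau181"),
    "plasma_ab42_40": ("plasma_ab42", "plasma_ab40"),
}

CSF_MARKERS = ["csf_ab42", "csf_ab40", "csf_ttau", "csf_ptau181",
               "csf_ab42_ttau", "csf_ab42_ptau"]
PLASMA_MARKERS = ["plasma_ab42", "plasma_ab40", "plasma_ab42_40",
                  "plasma_ptau181", "plasma_ptau217", "plasma_nfl"]

#: columns a subject must have to be included (mirrors the inclusion rule:
#: complete data on all biomarkers, age and sex)
COMPLETENESS_COLUMNS = BIOMARKER_COLUMNS + ["age", "sex"]

CANONICAL_COLUMNS = [
    "id", "age", "sex", "education", "mmse", "apoe_e4", "diagnosis",
] + BIOMARKER_COLUMNS

_SEX_VALUES = {"male", "female"}
_APOE_VALUES = {"carrier", "noncarrier"}
_DX_VALUES = {"MCI", "dementia"}


class CohortValidationError(ValueError):
    """Raised when a cohort table violates the subject-level invariants."""


@dataclass(frozen=True)
class ReferenceStandard:
    """Binary reference label: a CSF measure, a cut-off and the normal side.

    ``normal_direction`` is the side of the cut-off that is *normal* (A-).
    Values strictly on the normal side are A-; the boundary is abnormal.
    """

    measure: str
    cutoff: float
    normal_direction: str = "above"

    def __post_init__(self) -> None:
        if self.cutoff <= 0:
            raise ValueError(f"cutoff must be positive, got {self.cutoff}")
        if self.normal_direction not in {"above", "below"}:
            raise ValueError(
                f"normal_direction must be 'above' or 'below', got "
                f"{self.normal_direction!r}"
            )


CSF_AB42_40_STANDARD = ReferenceStandard("csf_ab42_40", AMYLOID_RATIO_CUTOFF, "above")
CSF_AB42_PTAU_STANDARD = ReferenceStandard("csf_ab42_ptau", CSF_AB42_PTAU_CUTOFF, "above")


@dataclass(frozen=True)
class ATProfile:
    a_status: str  # "Apos" | "Aneg"
    t_status: str  # "Tpos" | "Tneg"

    def __str__(self) -> str:  # e.g. "A+T-"
        return ("A+" if self.a_status == "Apos" else "A-") + (
            "T+" if self.t_status == "Tpos" else "T-")


def classify_amyloid(ratio, standard: ReferenceStandard = CSF_AB42_40_STANDARD):
    """Classify a ratio value (or array) as "Apos"/"Aneg" against a standard.

    A value strictly on the normal side of the cut-off is "Aneg"; a value at
    the cut-off or beyond is "Apos" (normal ranges are strict inequalities).
    """
    arr = np.asarray(ratio, dtype=float)
    if np.any(~np.isfinite(arr)) or np.any(arr <= 0):
        raise CohortValidationError(
            f"{standard.measure}: ratios must be positive finite values")
    if standard.normal_direction == "above":
        normal = arr > standard.cutoff
    else:
        normal = arr < standard.cutoff
    out = np.where(normal, "Aneg", "Apos")
    return out.item() if np.isscalar(ratio) else out


def classify_at(subject: Mapping) -> ATProfile:
    """AT profile of one subject (mapping/Series with the CSF columns).

    A status: CSF Abeta42/40 vs 0.069 (strictly above is normal).
    T status: CSF pTau181 >= 56.5 pg/ml is T+.
    """
    try:
        if "csf_ab42_40" in subject and not pd.isna(subject["csf_ab42_40"]):
            ratio = float(subject["csf_ab42_40"])
        else:
            ratio = float(subject["csf_ab42"]) / float(subject["csf_ab40"])
        ptau = float(subject["csf_ptau181"])
    except (KeyError, TypeError, ValueError) as exc:
        raise CohortValidationError(
            "classify_at needs csf_ab42_40 (or csf_ab42 and csf_ab40) "
            "and csf_ptau181") from exc
    if pd.isna(ratio) or pd.isna(ptau):
        raise CohortValidationError("classify_at inputs must not be missing")
    a = classify_amyloid(ratio)
    t = "Tpos" if ptau >= CSF_PTAU181_CUTOFF else "Tneg"
    return ATProfile(a_status=a, t_status=t)


class CohortTable:
    """Validated subject table with derived ratio columns.

    Wraps a :class:`pandas.DataFrame` (attribute ``df``).  Construction
    validates invariants (positive concentrations, age > 0, MMSE in [0, 30]
    when present, unique ids, categorical levels) and (re)computes the four
    derived ratios from the raw concentrations.
    """

    def __init__(self, df: pd.DataFrame, n_excluded: int = 0):
        df = df.copy().reset_index(drop=True)
        missing_cols = [c for c in CANONICAL_COLUMNS if c not in df.columns]
        if missing_cols:
            raise CohortValidationError(f"missing required columns: {missing_cols}")
        df["id"] = df["id"].astype(str)
        if df["id"].duplicated().any():
            dupes = df.loc[df["id"].duplicated(), "id"].tolist()
            raise CohortValidationError(f"duplicate subject ids: {dupes}")
        for col in BIOMARKER_COLUMNS + ["age", "education", "mmse"]:
            df[col] = pd.to_numeric(df[col], errors="raise")
        for col in BIOMARKER_COLUMNS:
            bad = df.index[df[col].notna() & (df[col] <= 0)]
            if len(bad):
                raise CohortValidationError(
                    f"nonpositive concentration in column {col!r}, row {bad[0]}")
        if (df["age"].notna() & (df["age"] <= 0)).any():
            raise CohortValidationError("age must be > 0")
        bad_mmse = df["mmse"].notna() & ~df["mmse"].between(0, 30)
        if bad_mmse.any():
            raise CohortValidationError("mmse must lie in [0, 30]")
        for col, allowed in (("sex", _SEX_VALUES), ("apoe_e4", _APOE_VALUES),
                             ("diagnosis", _DX_VALUES)):
            vals = set(df[col].dropna().unique()) - allowed
            if vals:
                raise CohortValidationError(
                    f"invalid value(s) {sorted(vals)} in column {col!r}")
        for ratio, (num, den) in DERIVED_RATIOS.items():
            df[ratio] = df[num] / df[den]
        self.df = df
        self.n_excluded = int(n_excluded)

    def __len__(self) -> int:
        return len(self.df)

    def __repr__(self) -> str:
        return f"CohortTable(n={len(self)}, n_excluded={self.n_excluded})"

    @property
    def columns(self) -> list[str]:
        return list(self.df.columns)

    def write_csv(self, path) -> None:
        """Write the cohort (including derived ratios) as CSV, full precision."""
        self.df.to_csv(path, index=False)

    def at_crosstab(self) -> pd.DataFrame:
        """2x2 table of AT profiles (rows A-, A+; columns T-, T+)."""
        profiles = [classify_at(row) for _, row in self.df.iterrows()]
        a = pd.Categorical([p.a_status for p in profiles], ["Aneg", "Apos"])
        t = pd.Categorical([p.t_status for p in profiles], ["Tneg", "Tpos"])
        return pd.crosstab(a, t, rownames=["A"], colnames=["T"], dropna=False)


def read_cohort(path, schema: Mapping[str, str] | None = None) -> CohortTable:
    """Read and validate a cohort CSV.

    Parameters
    ----------
    path
        CSV file with a header row (comma-separated, UTF-8, decimal point).
    schema
        Optional map from canonical column name to the name used in the file
        (for nonstandard headers).

    Rows missing any biomarker, age or sex are excluded (not an error) and
    counted in ``CohortTable.n_excluded``, mirroring the study's inclusion
    rule.  Non-numeric or nonpositive biomarker entries raise
    :class:`CohortValidationError` naming the row and column.
    """
    try:
        raw = pd.read_csv(path, dtype=str, skipinitialspace=True)
    except OSError as exc:
        raise OSError(f"cannot read cohort file {path}: {exc}") from exc
    if schema:
        raw = raw.rename(columns={v: k for k, v in schema.items()})
    missing = [c for c in CANONICAL_COLUMNS if c not in raw.columns]
    if missing:
        raise CohortValidationError(f"missing required columns: {missing}")
    df = raw[CANONICAL_COLUMNS].copy()
    for col in BIOMARKER_COLUMNS + ["age", "education", "mmse"]:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[df[col].notna() & coerced.isna()]
        if len(bad):
            raise CohortValidationError(
                f"non-numeric value {df.loc[bad[0], col]!r} in column "
                f"{col!r}, row {bad[0]}")
        df[col] = coerced
    for col in ("sex", "apoe_e4", "diagnosis"):
        df[col] = df[col].where(df[col].notna() & (df[col] != ""), other=np.nan)
    for col in BIOMARKER_COLUMNS:
        bad = df.index[df[col].notna() & (df[col] <= 0)]
        if len(bad):
            raise CohortValidationError(
                f"nonpositive concentration in column {col!r}, row {bad[0]} "
                f"(ratios would be undefined)")
    complete = df[COMPLETENESS_COLUMNS].notna().all(axis=1)
    n_excluded = int((~complete).sum())
    df = df.loc[complete]
    if df.empty:
        raise CohortValidationError("no complete rows in cohort file")
    return CohortTable(df, n_excluded=n_excluded)


def label_cohort(cohort: CohortTable,
                 standard: ReferenceStandard = CSF_AB42_40_STANDARD,
                 subset: str = "all") -> CohortTable:
    """Attach the binary amyloid reference label; optionally keep MCI only.

    Adds columns ``a_status`` ("Apos"/"Aneg") and ``a_positive`` (0/1 int)
    derived from ``standard``.  ``subset="MCI"`` restricts to subjects with
    an MCI diagnosis (the study's sensitivity analysis); subjects with a
    missing diagnosis are excluded only by that subset, never by "all".
    """
    if subset not in {"all", "MCI"}:
        raise ValueError(f"subset must be 'all' or 'MCI', got {subset!r}")
    df = cohort.df.copy()
    if subset == "MCI":
        df = df[df["diagnosis"] == "MCI"]
        if df.empty:
            raise CohortValidationError("no MCI subjects after subsetting")
    if standard.measure not in df.columns:
        raise CohortValidationError(
            f"reference measure {standard.measure!r} not in cohort")
    status = classify_amyloid(df[standard.measure].to_numpy(), standard)
    df = df.assign(a_status=status, a_positive=(status == "Apos").astype(int))
    out = CohortTable(df, n_excluded=cohort.n_excluded)
    return out


def split_groups(cohort: CohortTable, column: str) -> tuple[np.ndarray, np.ndarray]:
    """(A- values, A+ values) of one column from a labeled cohort."""
    df = cohort.df
    if "a_positive" not in df.columns:
        raise CohortValidationError("cohort is not labeled; call label_cohort first")
    neg = df.loc[df["a_positive"] == 0, column].to_numpy(dtype=float)
    pos = df.loc[df["a_positive"] == 1, column].to_numpy(dtype=float)
    return neg, pos
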