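"""Patient cohort I/O and validation.

A cohort is a table with one row per glioblastoma patient carrying the
pyrosequencing methylation readout (percent methylation at CpGs 76-79 of the
MGMT promoter and/or their mean), baseline covariates (age, sex, preoperative
ECOG performance status, extent of resection) and the censored overall
survival outcome in months.

Canonical CSV schema (header names case-insensitive, extra columns ignored)::

    patient_id, cpg76, cpg77, cpg78, cpg79, mean_meth,
    age, sex, preop_ps, resection, os_months, event

``mean_meth`` is recomputed from the four CpG columns when absent.  The four
CpG columns may be absent altogether ("mean-only mode") as long as
``mean_meth`` is present; per-CpG operations then raise
:class:`~pyrotier.errors.MissingPerCpGError`.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import EmptyCohortError, SchemaError

CPG_COLUMNS = ["cpg76", "cpg77", "cpg78", "cpg79"]
#: Canonical column order for on-disk cohort CSV files.
SCHEMA_COLUMNS = [
    "patient_id",
    *CPG_COLUMNS,
    "mean_meth",
    "age",
    "sex",
    "preop_ps",
    "resection",
    "os_months",
    "event",
]
MANDATORY_COLUMNS = [
    "patient_id", "age", "sex", "preop_ps", "resection", "os_months", "event",
]
SEX_LEVELS = ["male", "female"]
RESECTION_LEVELS = ["GTR", "NTR", "STR", "biopsy"]
_RESECTION_LOOKUP = {lvl.lower(): lvl for lvl in RESECTION_LEVELS}

#: Absolute tolerance when checking a supplied mean against the recomputed
#: mean of the four CpG values; 0.51 admits means rounded to integer percent.
MEAN_METH_TOLERANCE = 0.51


@dataclass(frozen=True)
class PatientRecord:
    """One subject's methylation values, covariates and survival outcome."""

    patient_id: str
    cpg_meth: tuple | None  # (cpg76..cpg79) percentages, None in mean-only mode
    mean_meth: float
    age: float
    sex: str
    preop_ps: int
    resection: str
    os_months: float
    event: int


@dataclass
class RejectionSummary:
    """Per-row validation outcomes; every rejected row appears exactly once."""

    n_input: int = 0
    n_accepted: int = 0
    reasons: dict = field(default_factory=dict)  # row label -> reason code

    @property
    def n_rejected(self) -> int:
        return self.n_input - self.n_accepted


class Cohort:
    """Ordered collection of validated patient records.

    Thin wrapper around a :class:`pandas.DataFrame` in canonical column
    order.  ``patient_id`` values are unique; analysis operations require a
    non-empty cohort.
    """

    def __init__(self, df: pd.DataFrame, provenance: str = "",
                 rejections: RejectionSummary | None = None):
        self.df = df.reset_index(drop=True)
        self.provenance = provenance
        self.rejections = rejections or RejectionSummary(
            n_input=len(df), n_accepted=len(df))

    def __len__(self) -> int:
        return len(self.df)

    @property
    def has_cpg(self) -> bool:
        """True when per-CpG methylation columns are available."""
        return all(c in self.df.columns and self.df[c].notna().all()
                   for c in CPG_COLUMNS)

    @property
    def records(self) -> list[PatientRecord]:
        recs = []
        for _, row in self.df.iterrows():
            cpg = (tuple(float(row[c]) for c in CPG_COLUMNS)
                   if self.has_cpg else None)
            recs.append(PatientRecord(
                patient_id=str(row["patient_id"]), cpg_meth=cpg,
                mean_meth=float(row["mean_meth"]), age=float(row["age"]),
                sex=str(row["sex"]), preop_ps=int(row["preop_ps"]),
                resection=str(row["resection"]),
                os_months=float(row["os_months"]), event=int(row["event"])))
        return recs

    def require_nonempty(self, context: str = "analysis") -> None:
        if len(self) == 0:
            raise EmptyCohortError(f"empty cohort in {context} context")


def _validate_row(row: pd.Series, has_cpg_cols: bool) -> str | None:
    """Return a reason code for an invalid row, or None when valid."""
    meth_cols = CPG_COLUMNS if has_cpg_cols else []
    for c in meth_cols:
        v = row[c]
        if pd.isna(v) or not np.isfinite(v) or not (0.0 <= v <= 100.0):
            return f"invalid_{c}"
    if has_cpg_cols:
        recomputed = float(np.mean([row[c] for c in CPG_COLUMNS]))
        if pd.isna(row["mean_meth"]):
            row["mean_meth"] = recomputed
        elif abs(float(row["mean_meth"]) - recomputed) > MEAN_METH_TOLERANCE:
            return "mean_meth_mismatch"
    else:
        if pd.isna(row["mean_meth"]):
            return "missing_mean_meth"
    m = float(row["mean_meth"])
    if not np.isfinite(m) or not (0.0 <= m <= 100.0):
        return "invalid_mean_meth"
    if pd.isna(row["age"]) or not (0.0 < float(row["age"])):
        return "invalid_age"
    if str(row["sex"]).lower() not in SEX_LEVELS:
        return "invalid_sex"
    try:
        ps = int(row["preop_ps"])
    except (TypeError, ValueError):
        return "invalid_preop_ps"
    if pd.isna(row["preop_ps"]) or ps not in (0, 1, 2, 3, 4):
        return "invalid_preop_ps"
    if str(row["resection"]).lower() not in _RESECTION_LOOKUP:
        return "invalid_resection"
    if pd.isna(row["os_months"]) or not (float(row["os_months"]) > 0.0):
        return "invalid_os_months"
    try:
        ev = int(row["event"])
    except (TypeError, ValueError):
        return "invalid_event"
    if pd.isna(row["event"]) or ev not in (0, 1):
        return "invalid_event"
    return None


def validate_cohort_frame(df: pd.DataFrame, strict: bool = False,
                          provenance: str = "") -> Cohort:
    """Validate a raw cohort frame into a :class:`Cohort`.

    In non-strict mode rows failing any invariant are dropped and counted in
    the returned cohort's rejection summary; in strict mode the first
    violation raises :class:`SchemaError`.
    """
    df = df.copy()
    df.columns = [str(c).strip().lower() for c in df.columns]
    for col in MANDATORY_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")
    has_cpg_cols = all(c in df.columns for c in CPG_COLUMNS)
    if not has_cpg_cols and "mean_meth" not in df.columns:
        raise SchemaError(
            "missing mandatory column: 'mean_meth' (required when per-CpG "
            "columns cpg76..cpg79 are absent)")
    keep = [c for c in SCHEMA_COLUMNS if c in df.columns]
    df = df[keep]
    if "mean_meth" not in df.columns:
        df["mean_meth"] = np.nan
    for c in CPG_COLUMNS + ["mean_meth", "age", "os_months"]:
        if c in df.columns:
            df[c] = pd.to_numeric(df[c], errors="coerce").astype(float)

    summary = RejectionSummary(n_input=len(df))
    rows = []
    for label, row in df.iterrows():
        row = row.copy()
        reason = _validate_row(row, has_cpg_cols)
        if reason is None:
            row["sex"] = str(row["sex"]).lower()
            row["resection"] = _RESECTION_LOOKUP[str(row["resection"]).lower()]
            row["preop_ps"] = int(row["preop_ps"])
            row["event"] = int(row["event"])
            rows.append(row)
        else:
            if strict:
                raise SchemaError(f"row {label!r}: {reason}")
            summary.reasons[label] = reason
    out = pd.DataFrame(rows, columns=df.columns)
    if len(out) and out["patient_id"].duplicated().any():
        dup = out["patient_id"].duplicated(keep="first")
        if strict:
            raise SchemaError("duplicate patient_id values")
        for label in out.index[dup]:
            summary.reasons[label] = "duplicate_patient_id"
        out = out[~dup]
    summary.n_accepted = len(out)
    return Cohort(out, provenance=provenance, rejections=summary)


def read_cohort(path, strict: bool = False) -> Cohort:
    """Read and validate a cohort CSV file.

    Parameters
    ----------
    path : path-like
        CSV file with a header row matching the documented schema
        (case-insensitive column names; extra columns ignored).
    strict : bool
        When True, any invalid row or duplicate id raises
        :class:`SchemaError`; otherwise offending rows are dropped and
        reported in ``cohort.rejections``.
    """
    try:
        raw = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise SchemaError(f"{path}: no header row") from exc
    return validate_cohort_frame(raw, strict=strict, provenance=str(path))


def write_cohort(cohort: Cohort, path) -> None:
    """Write a cohort CSV in canonical column order.

    Numeric fields are stored with enough digits that a round-trip through
    :func:`read_cohort` reproduces them to 6 significant figures.
    """
    df = cohort.df.copy()
    for col in SCHEMA_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan
    df = df[SCHEMA_COLUMNS]
    df.to_csv(path, index=False, float_format="%.6g")


def summarize_cohort(cohort: Cohort) -> dict:
    """Counts, medians and category frequencies of a cohort.

    Returns a dict with ``n``, median/range of age and mean methylation,
    event count, and count/percentage tables for sex, performance status and
    extent of resection (percentages sum to 100 up to rounding).
    """
    cohort.require_nonempty("summary")
    df = cohort.df
    n = len(df)

    def cat_table(col, levels):
        counts = df[col].value_counts()
        return {str(lvl): {"n": int(counts.get(lvl, 0)),
                           "pct": round(100.0 * counts.get(lvl, 0) / n, 1)}
                for lvl in levels}

    return {
        "n": n,
        "age": {"median": float(df["age"].median()),
                "range": (float(df["age"].min()), float(df["age"].max()))},
        "mean_meth": {"median": float(df["mean_meth"].median()),
                      "range": (float(df["mean_meth"].min()),
                                float(df["mean_meth"].max()))},
        "n_events": int(df["event"].sum()),
        "sex": cat_table("sex", SEX_LEVELS),
        "preop_ps": cat_table("preop_ps", [0, 1, 2, 3, 4]),
        "resection": cat_table("resection", RESECTION_LEVELS),
    }
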