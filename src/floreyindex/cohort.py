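"""Longitudinal cohort containers, CSV ingest, eligibility filtering and CDR-SB staging.

The expected input is a long-format visit table: one row per assessment with a
participant identifier, age at visit (decimal years), CDR-SB score (0-18 in
0.5-point steps), and optionally MMSE, a clinician diagnosis label and baseline
covariates (sex, APOE e4 carriage, comorbidity flags, education).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd

#: Clinical staging cut points on the CDR-SB scale.
MCI_CUT = 0.5
AD_CUT = 4.5
CDRSB_MAX = 18.0
MMSE_MAX = 30.0

#: Optional per-participant covariate columns understood by the pipeline.
COVARIATE_FIELDS = (
    "sex",
    "apoe_e4",
    "hypertension",
    "stroke",
    "neurologic",
    "psychiatric",
    "education_years",
    "non_ad_etiology",
)

#: Default logical-name -> CSV-column mapping; override via the ``schema``
#: argument of :func:`read_cohort`.
DEFAULT_SCHEMA: dict[str, str] = {
    "participant_id": "participant_id",
    "age": "age",
    "cdr_sb": "cdr_sb",
    "mmse": "mmse",
    "diagnosis": "diagnosis",
    **{c: c for c in COVARIATE_FIELDS},
}


class Stage(str, Enum):
    """Cognitive stage label."""

    CU = "CU"
    MCI = "MCI"
    AD = "AD"
    OTHER = "OTHER"


class SchemaError(ValueError):
    """A required column is missing from the input table."""


def stage_from_cdrsb(score: float) -> Stage:
    """Stage a CDR-SB score: CU below 0.5, MCI in [0.5, 4.5], AD above 4.5.

    Raises
    ------
    ValueError
        If ``score`` is outside the CDR-SB domain [0, 18].
    """
    if not np.isfinite(score) or not 0.0 <= score <= CDRSB_MAX:
        raise ValueError(f"CDR-SB score {score!r} outside [0, {CDRSB_MAX:g}]")
    if score < MCI_CUT:
        return Stage.CU
    if score <= AD_CUT:
        return Stage.MCI
    return Stage.AD


@dataclass(frozen=True)
class VisitRecord:
    """One assessment visit."""

    participant_id: str
    age: float
    cdr_sb: float
    mmse: float | None = None
    diagnosis: Stage | None = None

    def __post_init__(self) -> None:
        if not np.isfinite(self.age) or self.age <= 0:
            raise ValueError(f"age must be positive, got {self.age!r}")
        if not np.isfinite(self.cdr_sb) or not 0.0 <= self.cdr_sb <= CDRSB_MAX:
            raise ValueError(f"cdr_sb {self.cdr_sb!r} outside [0, {CDRSB_MAX:g}]")
        if self.mmse is not None and not 0.0 <= self.mmse <= MMSE_MAX:
            raise ValueError(f"mmse {self.mmse!r} outside [0, {MMSE_MAX:g}]")


@dataclass
class ParticipantSeries:
    """All visits of one participant, ordered by strictly increasing age."""

    participant_id: str
    visits: list[VisitRecord]
    covariates: dict[str, object] = field(default_factory=dict)

    def __post_init__(self) -> None:
        ages = [v.age for v in self.visits]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError(
                f"{self.participant_id}: visit ages must be strictly increasing"
            )
        for v in self.visits:
            if v.participant_id != self.participant_id:
                raise ValueError("visit participant_id mismatch")

    @property
    def ages(self) -> np.ndarray:
        return np.array([v.age for v in self.visits], dtype=float)

    @property
    def scores(self) -> np.ndarray:
        return np.array([v.cdr_sb for v in self.visits], dtype=float)

    @property
    def n_visits(self) -> int:
        return len(self.visits)

    def truncate_before(self, age: float) -> "ParticipantSeries":
        """Series restricted to visits with age strictly below ``age``."""
        kept = [v for v in self.visits if v.age < age]
        return ParticipantSeries(self.participant_id, kept, dict(self.covariates))


@dataclass
class Cohort:
    """A collection of participant series with unique identifiers."""

    series: list[ParticipantSeries]
    provenance: str = ""

    def __post_init__(self) -> None:
        ids = [s.participant_id for s in self.series]
        if len(set(ids)) != len(ids):
            raise ValueError("participant_ids must be unique within a cohort")

    def __len__(self) -> int:
        return len(self.series)

    def __iter__(self):
        return iter(self.series)

    @property
    def participant_ids(self) -> list[str]:
        return [s.participant_id for s in self.series]

    def get(self, participant_id: str) -> ParticipantSeries:
        for s in self.series:
            if s.participant_id == participant_id:
                return s
        raise KeyError(participant_id)


@dataclass(frozen=True)
class RejectedRow:
    """A row that failed validation during ingest, with the reason."""

    row_index: int
    participant_id: str | None
    reason: str


def _parse_bool(value) -> bool | None:
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return None
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    if isinstance(value, (int, float, np.integer, np.floating)):
        return bool(int(value))
    s = str(value).strip().lower()
    if s in {"1", "true", "t", "yes", "y"}:
        return True
    if s in {"0", "false", "f", "no", "n"}:
        return False
    return None


def _is_missing(value) -> bool:
    return value is None or (isinstance(value, float) and np.isnan(value)) or (
        isinstance(value, str) and value.strip() == ""
    )


def read_cohort(
    path: str | Path,
    schema: Mapping[str, str] | None = None,
) -> tuple[Cohort, list[RejectedRow]]:
    """Read a long-format visit CSV into a :class:`Cohort`.

    Rows that cannot be validated (non-numeric age or score, out-of-range
    values, unknown diagnosis labels, duplicated visit ages) are collected in
    the returned reject list rather than silently dropped. Visits are grouped
    per participant and sorted ascending by age; covariates are taken from the
    first non-missing value per participant.

    Returns
    -------
    (cohort, rejects)
    """
    colmap = dict(DEFAULT_SCHEMA)
    if schema:
        colmap.update(schema)
    path = Path(path)
    df = pd.read_csv(path, dtype={colmap["participant_id"]: str})

    for logical in ("participant_id", "age", "cdr_sb"):
        if colmap[logical] not in df.columns:
            raise SchemaError(f"required column {colmap[logical]!r} missing from {path}")

    rejects: list[RejectedRow] = []
    rows: list[dict] = []
    off_grid = 0
    for idx, row in df.iterrows():
        pid = row[colmap["participant_id"]]
        if _is_missing(pid):
            rejects.append(RejectedRow(int(idx), None, "missing participant_id"))
            continue
        pid = str(pid).strip()
        try:
            age = float(row[colmap["age"]])
        except (TypeError, ValueError):
            rejects.append(RejectedRow(int(idx), pid, "non-numeric age"))
            continue
        if not np.isfinite(age) or age <= 0:
            rejects.append(RejectedRow(int(idx), pid, "non-positive age"))
            continue
        try:
            cdr_sb = float(row[colmap["cdr_sb"]])
        except (TypeError, ValueError):
            rejects.append(RejectedRow(int(idx), pid, "non-numeric cdr_sb"))
            continue
        if not np.isfinite(cdr_sb) or not 0.0 <= cdr_sb <= CDRSB_MAX:
            rejects.append(
                RejectedRow(int(idx), pid, "score out of range [0,18]")
            )
            continue
        if abs(cdr_sb * 2 - round(cdr_sb * 2)) > 1e-9:
            off_grid += 1

        mmse = None
        if colmap["mmse"] in df.columns and not _is_missing(row[colmap["mmse"]]):
            try:
                mmse = float(row[colmap["mmse"]])
            except (TypeError, ValueError):
                rejects.append(RejectedRow(int(idx), pid, "non-numeric mmse"))
                continue
            if not 0.0 <= mmse <= MMSE_MAX:
                rejects.append(RejectedRow(int(idx), pid, "mmse out of range [0,30]"))
                continue

        diagnosis = None
        if colmap["diagnosis"] in df.columns and not _is_missing(
            row[colmap["diagnosis"]]
        ):
            label = str(row[colmap["diagnosis"]]).strip().upper()
            try:
                diagnosis = Stage(label)
            except ValueError:
                rejects.append(
                    RejectedRow(int(idx), pid, f"unknown diagnosis label {label!r}")
                )
                continue

        cov: dict[str, object] = {}
        for name in COVARIATE_FIELDS:
            col = colmap[name]
            if col not in df.columns or _is_missing(row[col]):
                continue
            if name == "sex":
                s = str(row[col]).strip().upper()
                if s in {"F", "M"}:
                    cov[name] = s
            elif name == "education_years":
                try:
                    cov[name] = float(row[col])
                except (TypeError, ValueError):
                    pass
            else:
                b = _parse_bool(row[col])
                if b is not None:
                    cov[name] = b

        rows.append(
            {"idx": int(idx), "pid": pid, "age": age, "cdr_sb": cdr_sb,
             "mmse": mmse, "diagnosis": diagnosis, "cov": cov}
        )

    if off_grid:
        warnings.warn(
            f"{off_grid} CDR-SB values are not on the 0.5-point grid; accepted as-is",
            stacklevel=2,
        )

    series: list[ParticipantSeries] = []
    by_pid: dict[str, list[dict]] = {}
    for r in rows:
        by_pid.setdefault(r["pid"], []).append(r)
    for pid, group in by_pid.items():
        group.sort(key=lambda r: (r["age"], r["idx"]))
        covariates: dict[str, object] = {}
        visits: list[VisitRecord] = []
        seen_ages: set[float] = set()
        for r in group:
            if r["age"] in seen_ages:
                rejects.append(RejectedRow(r["idx"], pid, "duplicate visit age"))
                continue
            seen_ages.add(r["age"])
            visits.append(
                VisitRecord(pid, r["age"], r["cdr_sb"], r["mmse"], r["diagnosis"])
            )
            for k, v in r["cov"].items():
                covariates.setdefault(k, v)
        if visits:
            series.append(ParticipantSeries(pid, visits, covariates))

    cohort = Cohort(series, provenance=f"read_cohort({path.name})")
    return cohort, rejects


def write_cohort(cohort: Cohort, path: str | Path) -> Path:
    """Write a cohort back to long-format CSV (inverse of :func:`read_cohort`)."""
    records = []
    for s in cohort:
        for v in s.visits:
            rec = {
                "participant_id": s.participant_id,
                "age": v.age,
                "cdr_sb": v.cdr_sb,
                "mmse": v.mmse,
                "diagnosis": v.diagnosis.value if v.diagnosis else None,
            }
            for name in COVARIATE_FIELDS:
                if name in s.covariates:
                    val = s.covariates[name]
                    rec[name] = int(val) if isinstance(val, bool) else val
            records.append(rec)
    frame = pd.DataFrame.from_records(records)
    frame = frame.dropna(axis=1, how="all")
    path = Path(path)
    frame.to_csv(path, index=False)
    return path


@dataclass
class ExclusionReport:
    """Counts of participants removed by each eligibility rule."""

    n_input: int
    n_retained: int
    counts: dict[str, int]
    excluded_ids: dict[str, list[str]]


def apply_eligibility(
    cohort: Cohort,
    min_age: float = 60.0,
    min_visits: int = 2,
    exclude_non_ad: bool = True,
) -> tuple[Cohort, ExclusionReport]:
    """Apply enrolment rules: first visit after ``min_age``, at least
    ``min_visits`` CDR-SB records, and (optionally) no non-Alzheimer etiology.

    Rules are checked in the order min_age, min_visits, non_ad_etiology; a
    participant is counted under the first rule it fails. The operation is
    idempotent.
    """
    rules = ("min_age", "min_visits", "non_ad_etiology")
    counts = {r: 0 for r in rules}
    excluded: dict[str, list[str]] = {r: [] for r in rules}
    kept: list[ParticipantSeries] = []
    for s in cohort:
        if not s.visits or s.visits[0].age <= min_age:
            counts["min_age"] += 1
            excluded["min_age"].append(s.participant_id)
            continue
        if s.n_visits < min_visits:
            counts["min_visits"] += 1
            excluded["min_visits"].append(s.participant_id)
            continue
        if exclude_non_ad and bool(s.covariates.get("non_ad_etiology", False)):
            counts["non_ad_etiology"] += 1
            excluded["non_ad_etiology"].append(s.participant_id)
            continue
        kept.append(s)
    if not kept:
        warnings.warn("eligibility filtering removed every participant", stacklevel=2)
    out = Cohort(kept, provenance=cohort.provenance)
    return out, ExclusionReport(len(cohort), len(kept), counts, excluded)
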