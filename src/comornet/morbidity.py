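"""Encounter-level ICD-9 diagnosis records -> binary morbidity matrix.

Raw EHR diagnosis tables are long-format: one row per (encounter, ICD-9
code).  Preprocessing consolidates codes to broad diagnosis categories
(3-digit numeric prefix, V + two digits, E + three digits), keeps only each
patient's last encounter so rows are independent, builds the N x P binary
indicator matrix, drops rare categories (frequency below ``min_count``),
and removes rows left without any diagnosis.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .containers import MorbidityMatrix

__all__ = [
    "EncounterRecord",
    "consolidate_icd9",
    "select_last_encounter",
    "build_matrix",
    "ExclusionReport",
]

logger = logging.getLogger(__name__)

_NUMERIC_RE = re.compile(r"^\d{3,5}$")
_V_RE = re.compile(r"^V\d{2,4}$")
_E_RE = re.compile(r"^E\d{3,4}$")


@dataclass
class EncounterRecord:
    """One hospital encounter with its diagnosis codes."""

    patient_id: str
    encounter_id: str
    admit_time: datetime
    icd9_codes: list[str]


@dataclass
class ExclusionReport:
    """What the rare-category filter removed."""

    dropped_categories: dict[str, int] = field(default_factory=dict)
    dropped_rows: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "dropped_categories": self.dropped_categories,
            "dropped_rows": self.dropped_rows,
        }


def consolidate_icd9(code: str) -> str:
    """Consolidate an ICD-9 code to its general diagnosis category.

    Numeric codes keep their first three digits; V codes keep "V" plus the
    first two digits after it; E codes keep "E" plus the first three.  Dots
    are removed and letters uppercased first.  Malformed codes (empty,
    non-ICD-9 characters, too short to truncate) raise ValueError naming
    the offending code.

    >>> consolidate_icd9("4280")
    '428'
    >>> consolidate_icd9("V4511")
    'V45'
    >>> consolidate_icd9("E8120")
    'E812'
    """
    if not isinstance(code, str) or not code.strip():
        raise ValueError(f"malformed ICD-9 code: {code!r}")
    clean = code.strip().upper().replace(".", "")
    if _NUMERIC_RE.match(clean):
        return clean[:3]
    if _V_RE.match(clean):
        return clean[:3]
    if _E_RE.match(clean):
        return clean[:4]
    raise ValueError(f"malformed ICD-9 code: {code!r}")


def select_last_encounter(records: list[EncounterRecord]) -> list[EncounterRecord]:
    """Keep exactly one encounter per patient: the one with the latest
    admission time.  Ties on admission time are broken toward the
    lexicographically largest encounter id (deterministic and auditable);
    each tie is logged.  Input order of patients is preserved."""
    best: dict[str, EncounterRecord] = {}
    for rec in records:
        cur = best.get(rec.patient_id)
        if cur is None:
            best[rec.patient_id] = rec
            continue
        if rec.admit_time > cur.admit_time:
            best[rec.patient_id] = rec
        elif rec.admit_time == cur.admit_time:
            logger.info(
                "patient %s: admit-time tie between encounters %s and %s",
                rec.patient_id, cur.encounter_id, rec.encounter_id,
            )
            if str(rec.encounter_id) > str(cur.encounter_id):
                best[rec.patient_id] = rec
    return list(best.values())


def build_matrix(
    records: list[EncounterRecord],
    min_count: int = 20,
    consolidate: bool = True,
) -> tuple[MorbidityMatrix, ExclusionReport]:
    """Build the binary patient-by-category matrix.

    Each cell is 1 iff the encounter carries at least one code mapping to
    that category (duplicates within an encounter collapse to a single
    indicator).  Categories occurring in fewer than ``min_count`` encounters
    are dropped; rows left all-zero after the drop are removed.  Both
    removals are returned in the exclusion report and logged.

    ``consolidate=False`` assumes codes are already category labels.
    """
    if not records:
        raise ValueError("no encounter records")
    if min_count < 1:
        raise ValueError("min_count must be >= 1")
    cat_sets: list[set[str]] = []
    for rec in records:
        if not rec.icd9_codes:
            raise ValueError(f"encounter {rec.encounter_id} has no diagnosis codes")
        cats = {consolidate_icd9(c) if consolidate else str(c) for c in rec.icd9_codes}
        cat_sets.append(cats)
    all_cats = sorted(set().union(*cat_sets))
    col = {c: k for k, c in enumerate(all_cats)}
    values = np.zeros((len(records), len(all_cats)), dtype=np.int8)
    for r, cats in enumerate(cat_sets):
        for c in cats:
            values[r, col[c]] = 1

    freqs = values.sum(axis=0)
    keep = freqs >= min_count
    report = ExclusionReport(
        dropped_categories={
            all_cats[k]: int(freqs[k]) for k in range(len(all_cats)) if not keep[k]
        }
    )
    values = values[:, keep]
    kept_cats = [c for c, k in zip(all_cats, keep) if k]
    if not kept_cats:
        raise ValueError(f"no category reaches min_count={min_count}")

    row_ok = values.sum(axis=1) >= 1
    report.dropped_rows = [records[r].patient_id for r in range(len(records)) if not row_ok[r]]
    values = values[row_ok]
    row_ids = [rec.patient_id for rec, ok in zip(records, row_ok) if ok]
    if report.dropped_categories:
        logger.info(
            "dropped %d categories below min_count=%d",
            len(report.dropped_categories), min_count,
        )
    if report.dropped_rows:
        logger.info("dropped %d rows with no remaining diagnosis", len(report.dropped_rows))
    return MorbidityMatrix(values=values, categories=kept_cats, row_ids=row_ids), report


def records_from_frame(frame: pd.DataFrame) -> list[EncounterRecord]:
    """Group a long-format diagnosis table (columns patient_id, encounter_id,
    admit_time, icd9_code) into encounter records.  Timestamps must parse as
    ISO-8601; anything unparsable is an error, never silently ordered."""
    required = {"patient_id", "encounter_id", "admit_time", "icd9_code"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"missing required columns: {sorted(missing)}")
    times = pd.to_datetime(frame["admit_time"], errors="coerce", format="ISO8601")
    if times.isna().any():
        bad = frame.loc[times.isna(), "admit_time"].iloc[0]
        raise ValueError(f"unparsable admit_time: {bad!r}")
    frame = frame.assign(_t=times)
    records = []
    for (pid, eid), grp in frame.groupby(["patient_id", "encounter_id"], sort=True):
        t = grp["_t"].unique()
        if len(t) > 1:
            raise ValueError(f"encounter {eid} has conflicting admit times")
        records.append(
            EncounterRecord(
                patient_id=str(pid),
                encounter_id=str(eid),
                admit_time=t[0].to_pydatetime(),
                icd9_codes=[str(c) for c in grp["icd9_code"]],
            )
        )
    return records
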