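"""Per-subject records and stage-to-score conversion.

A :class:`DentalRecord` carries what a panoramic-radiograph reading yields
for one subject: sex, chronological age (given directly or as birth/exam
dates), the developmental stage of each of the seven left mandibular teeth,
and/or a precomputed seven-tooth maturity score.  The two scoring operations
are plain sums over the sex-specific score table:
:func:`demirjian_total_score` (maturity points) and
:func:`willems_dental_age` (years).
"""

from __future__ import annotations

import datetime as _dt
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .reference_data import (
    TEETH,
    ScoreTable,
    normalize_sex,
    normalize_stage,
)

__all__ = [
    "DentalRecord",
    "RecordError",
    "BilateralAbsenceError",
    "chronological_age",
    "demirjian_total_score",
    "willems_dental_age",
    "substitute_contralateral",
    "read_records_csv",
    "write_records_csv",
    "RECORD_CSV_COLUMNS",
]

#: mirror of the left teeth on the right mandible (FDI quadrant 4)
CONTRALATERAL = {t: t + 10 for t in TEETH}

RECORD_CSV_COLUMNS = (
    ["subject_id", "sex", "dob", "exam_date", "ca_years"]
    + [f"t{t}" for t in TEETH]
    + [f"t{t + 10}" for t in TEETH]
    + ["maturity_score", "score_clamped"]
)


class RecordError(ValueError):
    """A record that cannot be used for the requested operation."""


class BilateralAbsenceError(RecordError):
    """Both the left tooth and its right-side counterpart are missing."""


def chronological_age(birth_date: _dt.date, exam_date: _dt.date) -> float:
    """Chronological age in years, two decimals.

    Computed as (exam - birth) in days divided by 365.25 and rounded
    half-even to two decimal places.  Raises if the examination precedes
    birth.
    """
    if exam_date < birth_date:
        raise ValueError(f"exam date {exam_date} precedes birth date {birth_date}")
    days = (exam_date - birth_date).days
    return round(days / 365.25, 2)


@dataclass
class DentalRecord:
    """One subject: identity, sex, age information and tooth development.

    At least one of ``stages`` / ``maturity_score`` must be present.  If both
    a chronological age and a date pair are supplied they must agree to
    0.01 y.  ``contralateral`` optionally holds stages of the mirrored right
    teeth (FDI 41-47) for gap substitution; ``score_clamped`` marks synthetic
    records whose true score was truncated at a model-domain edge.
    """

    subject_id: str
    sex: str
    chronological_age: float | None = None
    birth_date: _dt.date | None = None
    exam_date: _dt.date | None = None
    stages: dict[int, str] | None = None
    maturity_score: float | None = None
    contralateral: dict[int, str] | None = field(default=None, repr=False)
    score_clamped: bool = False

    def __post_init__(self) -> None:
        self.sex = normalize_sex(self.sex)
        if self.stages is None and self.maturity_score is None:
            raise RecordError(
                f"record {self.subject_id}: needs per-tooth stages or a maturity score"
            )
        if self.stages is not None:
            self.stages = {int(t): normalize_stage(s) for t, s in self.stages.items()}
        if self.contralateral is not None:
            self.contralateral = {int(t): normalize_stage(s) for t, s in self.contralateral.items()}
        if self.birth_date is not None and self.exam_date is not None:
            from_dates = chronological_age(self.birth_date, self.exam_date)
            if self.chronological_age is None:
                self.chronological_age = from_dates
            elif abs(self.chronological_age - from_dates) > 0.01 + 1e-9:
                raise RecordError(
                    f"record {self.subject_id}: stated age {self.chronological_age} "
                    f"disagrees with dates ({from_dates})"
                )


def _stage_vector(record: DentalRecord) -> dict[int, str]:
    if record.stages is None:
        raise RecordError(f"record {record.subject_id}: no per-tooth stages available")
    missing = [t for t in TEETH if t not in record.stages]
    if missing:
        raise RecordError(
            f"record {record.subject_id}: missing stages for teeth {missing}"
        )
    return record.stages


def _check_table(record: DentalRecord, table: ScoreTable, system: str) -> None:
    if table.system != system:
        raise ValueError(f"expected a {system} table, got {table.system!r}")
    if table.sex != record.sex:
        raise ValueError(
            f"record {record.subject_id} is sex {record.sex} but the table is for {table.sex}"
        )


def demirjian_total_score(record: DentalRecord, table: ScoreTable) -> float:
    """Seven-tooth total maturity score (dimensionless, 0 to the all-H max)."""
    _check_table(record, table, "demirjian")
    stages = _stage_vector(record)
    return sum(table.score(t, stages[t]) for t in TEETH)


def willems_dental_age(record: DentalRecord, table: ScoreTable) -> float:
    """Dental age in years as the plain sum of per-tooth age contributions."""
    _check_table(record, table, "willems")
    stages = _stage_vector(record)
    return sum(table.score(t, stages[t]) for t in TEETH)


def substitute_contralateral(
    stages: Mapping[int, str],
    contralateral: Mapping[int, str] | None,
) -> dict[int, str]:
    """Fill missing left-tooth stages from the mirrored right tooth.

    Mirrors the cohort exclusion rule: a tooth absent on both sides (other
    than the third molar, which is outside the system) makes the record
    unusable, raising :class:`BilateralAbsenceError`.
    """
    contralateral = dict(contralateral or {})
    out = {int(t): normalize_stage(s) for t, s in stages.items()}
    for tooth in TEETH:
        if tooth in out:
            continue
        mirror = CONTRALATERAL[tooth]
        if mirror not in contralateral:
            raise BilateralAbsenceError(
                f"tooth {tooth} missing and contralateral {mirror} also absent"
            )
        out[tooth] = normalize_stage(contralateral[mirror])
    return out


# ---------------------------------------------------------------------------
# CSV interchange

def _parse_date(value: str) -> _dt.date:
    return _dt.date.fromisoformat(value.strip())


def read_records_csv(path) -> tuple[list[DentalRecord], list[tuple[str, str]]]:
    """Read subject records from the standard CSV layout.

    Columns (header required; unknown columns ignored): ``subject_id``,
    ``sex``, ``dob``, ``exam_date``, ``ca_years``, ``t31``..``t37``,
    optionally ``t41``..``t47`` and ``maturity_score``.  Dates are ISO-8601.
    Unusable rows are not fatal: they are returned as
    ``(subject_id, reason)`` exclusions alongside the parsed records.
    """
    frame = pd.read_csv(path, dtype=str, comment="#", skip_blank_lines=True)
    records: list[DentalRecord] = []
    exclusions: list[tuple[str, str]] = []

    def cell(row, name):
        value = row.get(name)
        if value is None or (isinstance(value, float) and pd.isna(value)):
            return None
        value = str(value).strip()
        return value or None

    for idx, row in frame.iterrows():
        subject = cell(row, "subject_id") or f"row{idx + 1}"
        try:
            stages = {}
            for tooth in TEETH:
                value = cell(row, f"t{tooth}")
                if value is not None:
                    stages[tooth] = normalize_stage(value)
            contra = {}
            for tooth in TEETH:
                value = cell(row, f"t{tooth + 10}")
                if value is not None:
                    contra[tooth + 10] = normalize_stage(value)
            score = cell(row, "maturity_score")
            ca = cell(row, "ca_years")
            dob, exam = cell(row, "dob"), cell(row, "exam_date")
            clamped = (cell(row, "score_clamped") or "").lower() in ("1", "true", "yes")
            records.append(
                DentalRecord(
                    subject_id=subject,
                    sex=cell(row, "sex"),
                    chronological_age=float(ca) if ca is not None else None,
                    birth_date=_parse_date(dob) if dob else None,
                    exam_date=_parse_date(exam) if exam else None,
                    stages=stages or None,
                    maturity_score=float(score) if score is not None else None,
                    contralateral=contra or None,
                    score_clamped=clamped,
                )
            )
        except (ValueError, RecordError) as exc:
            exclusions.append((subject, str(exc)))
    return records, exclusions


def write_records_csv(records: Iterable[DentalRecord], path, *, header_comment: str | None = None) -> None:
    """Write records in the same CSV layout that :func:`read_records_csv` reads."""
    rows = []
    for r in records:
        row: dict[str, object] = {
            "subject_id": r.subject_id,
            "sex": r.sex,
            "dob": r.birth_date.isoformat() if r.birth_date else "",
            "exam_date": r.exam_date.isoformat() if r.exam_date else "",
            "ca_years": "" if r.chronological_age is None else f"{r.chronological_age:.2f}",
            "maturity_score": "" if r.maturity_score is None else repr(float(r.maturity_score)),
            "score_clamped": "true" if r.score_clamped else "",
        }
        for tooth in TEETH:
            row[f"t{tooth}"] = (r.stages or {}).get(tooth, "")
            row[f"t{tooth + 10}"] = (r.contralateral or {}).get(tooth + 10, "")
        rows.append(row)
    frame = pd.DataFrame(rows, columns=RECORD_CSV_COLUMNS)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)
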