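"""Reference constants and packaged lookup data for dental age estimation.

The estimation system rates each of the seven left mandibular permanent
teeth (FDI 31-37, central incisor through second molar) into nine
developmental stages -- ``0`` (no calcification visible) followed by ``A``
through ``H`` (crown formation through apex closure) -- on a panoramic
radiograph.  Stage ratings are converted to numeric scores through a
sex-specific :class:`ScoreTable` and summed.  Two scoring systems are
packaged:

* ``demirjian`` -- self-weighted maturity points; the seven-tooth total is a
  dimensionless maturity score whose all-``H`` maximum is 100.0 for boys and
  98.4 for girls,
* ``willems`` -- per-tooth age contributions in years whose plain sum is a
  dental age estimate (the packaged table is a clearly labelled synthetic
  stand-in, see its provenance string).

On top of the scores, sex-specific fifth-degree polynomials (maturity score
-> age, :class:`PolynomialModel`) and the score/age lookup tables generated
from the same reference population (:class:`ConversionTable`) are packaged.
All resources are plain JSON under ``dentage/data`` and can be replaced by
user-supplied files with the same schema.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from importlib import resources as _importlib_resources
from typing import Mapping

__all__ = [
    "TEETH",
    "STAGES",
    "STAGE_INDEX",
    "MALE",
    "FEMALE",
    "SEXES",
    "EXPECTED_ALL_H_TOTAL",
    "normalize_sex",
    "normalize_stage",
    "ScoreTable",
    "PolynomialModel",
    "TableRow",
    "ConversionTable",
    "ValidationReport",
    "load_builtin",
    "validate_score_table",
]

#: FDI codes of the seven left mandibular permanent teeth, incisor to molar.
#: The third molar (38) is deliberately excluded from the system.
TEETH: tuple[int, ...] = (31, 32, 33, 34, 35, 36, 37)

#: Developmental stage codes in maturation order. ``0`` = no calcification.
STAGES: tuple[str, ...] = ("0", "A", "B", "C", "D", "E", "F", "G", "H")

#: Total order on stages: STAGE_INDEX["0"] == 0 < ... < STAGE_INDEX["H"] == 8.
STAGE_INDEX: Mapping[str, int] = {s: i for i, s in enumerate(STAGES)}

MALE = "M"
FEMALE = "F"
SEXES: tuple[str, str] = (MALE, FEMALE)

#: Seven-tooth maturity-point total when every tooth is at stage H.
EXPECTED_ALL_H_TOTAL: Mapping[str, float] = {MALE: 100.0, FEMALE: 98.4}

_SEX_ALIASES = {
    "m": MALE, "male": MALE, "boy": MALE, "boys": MALE, "1": MALE,
    "f": FEMALE, "female": FEMALE, "girl": FEMALE, "girls": FEMALE, "2": FEMALE,
}


def normalize_sex(value: object) -> str:
    """Return the canonical sex code ``"M"`` or ``"F"``.

    Accepts the common spellings (``m/M/male/boy``, ``f/F/female/girl``);
    anything else raises :class:`ValueError`.
    """
    key = str(value).strip().lower()
    try:
        return _SEX_ALIASES[key]
    except KeyError:
        raise ValueError(f"unrecognized sex code: {value!r} (expected M or F)") from None


def normalize_stage(value: object) -> str:
    """Return the canonical stage code ``0`` or ``A``-``H``."""
    code = str(value).strip().upper()
    if code not in STAGE_INDEX:
        raise ValueError(f"unrecognized stage code: {value!r} (expected 0 or A-H)")
    return code


@dataclass(frozen=True)
class ScoreTable:
    """Sex-specific mapping (tooth, stage) -> numeric score.

    ``system`` is ``"demirjian"`` (dimensionless maturity points) or
    ``"willems"`` (age contributions in years).  ``entries`` must contain a
    score for every (tooth, stage) pair; stages below the first stage
    tabulated in the source literature carry zero points.
    """

    system: str
    sex: str
    entries: Mapping[tuple[int, str], float]
    provenance: str = ""

    def score(self, tooth: int, stage: str) -> float:
        """Score for one tooth at one stage; raises ``KeyError`` if absent."""
        key = (int(tooth), normalize_stage(stage))
        if key not in self.entries:
            raise KeyError(
                f"no {self.system} score for tooth {key[0]} at stage {key[1]} (sex {self.sex})"
            )
        return self.entries[key]

    def max_total(self) -> float:
        """Seven-tooth total with every tooth at stage H."""
        return sum(self.entries[(t, "H")] for t in TEETH)

    def min_total(self) -> float:
        """Seven-tooth total with every tooth at stage 0."""
        return sum(self.entries[(t, "0")] for t in TEETH)


@dataclass(frozen=True)
class PolynomialModel:
    """Sex-specific polynomial mapping maturity score ``x`` to age ``p(x)``.

    ``coefficients`` are stored in descending-degree order
    (p1..p(n+1) for degree n), exactly as published for the packaged models.
    ``score_domain`` is the closed score interval on which the model is
    intended to be used.  Monotonicity on the domain is a *reported* property
    (see :func:`dentage.conversion.polynomial_is_increasing`), not an
    enforced invariant: the packaged girls model has a shallow decreasing
    stretch inside its domain (an artefact of the unconstrained fit).
    """

    sex: str
    coefficients: tuple[float, ...]
    score_domain: tuple[float, float]
    provenance: str = ""

    def __post_init__(self) -> None:
        if len(self.coefficients) < 1:
            raise ValueError("a polynomial needs at least one coefficient")
        lo, hi = self.score_domain
        if not (math.isfinite(lo) and math.isfinite(hi) and lo < hi):
            raise ValueError(f"invalid score domain {self.score_domain}")

    @property
    def degree(self) -> int:
        return len(self.coefficients) - 1


@dataclass(frozen=True)
class TableRow:
    """One (age, score) row of a conversion table.

    ``flagged`` rows are transcription artefacts of the source tables (run-on
    digits, a score above the nominal maximum); they are stored verbatim but
    excluded from interpolation and from automated consistency checks, with
    the reason in ``note``.
    """

    age: float
    score: float
    flagged: bool = False
    note: str = ""


@dataclass(frozen=True)
class ConversionTable:
    """Ordered (age, score) rows mapping maturity score to dental age."""

    sex: str
    rows: tuple[TableRow, ...]
    provenance: str = ""

    def __post_init__(self) -> None:
        ages = [r.age for r in self.rows]
        if any(b <= a for a, b in zip(ages, ages[1:])):
            raise ValueError("conversion-table ages must be strictly increasing")

    def active_rows(self) -> tuple[TableRow, ...]:
        """Rows usable for lookup (flagged transcription artefacts removed)."""
        return tuple(r for r in self.rows if not r.flagged)


@dataclass
class ValidationReport:
    """Report-only structural check of a :class:`ScoreTable`."""

    system: str
    sex: str
    monotonicity_violations: list[str] = field(default_factory=list)
    missing_cells: list[tuple[int, str]] = field(default_factory=list)
    negative_scores: list[tuple[int, str]] = field(default_factory=list)
    all_h_total: float | None = None
    expected_all_h_total: float | None = None

    @property
    def all_h_ok(self) -> bool | None:
        if self.expected_all_h_total is None or self.all_h_total is None:
            return None
        return abs(self.all_h_total - self.expected_all_h_total) < 1e-9

    @property
    def ok(self) -> bool:
        return (
            not self.monotonicity_violations
            and not self.missing_cells
            and not self.negative_scores
            and self.all_h_ok is not False
        )


def validate_score_table(table: ScoreTable) -> ValidationReport:
    """Check completeness, per-tooth monotonicity and the all-H total.

    Never raises: every problem is collected into the returned
    :class:`ValidationReport`.  For Demirjian tables the all-``H`` seven-tooth
    total is compared against the system's nominal maxima (100.0 boys,
    98.4 girls).
    """
    report = ValidationReport(system=table.system, sex=table.sex)
    for tooth in TEETH:
        prev: float | None = None
        for stage in STAGES:
            if (tooth, stage) not in table.entries:
                report.missing_cells.append((tooth, stage))
                prev = None
                continue
            value = table.entries[(tooth, stage)]
            if value < 0:
                report.negative_scores.append((tooth, stage))
            if prev is not None and value < prev:
                report.monotonicity_violations.append(
                    f"tooth {tooth}: score decreases at stage {stage} ({prev} -> {value})"
                )
            prev = value
    if not any(t == tooth and s == "H" for (t, s) in report.missing_cells for tooth in TEETH):
        try:
            report.all_h_total = round(table.max_total(), 10)
        except KeyError:
            report.all_h_total = None
    if table.system == "demirjian":
        report.expected_all_h_total = EXPECTED_ALL_H_TOTAL.get(table.sex)
    return report


# ---------------------------------------------------------------------------
# packaged resources

_RESOURCE_FILES = {
    "demirjian": "demirjian_scores.json",
    "willems": "willems_scores_synthetic.json",
    "modified_polynomials": "modified_polynomials.json",
    "reference_tables": "conversion_tables_reference.json",
    "demirjian_conversion": "demirjian_conversion_synthetic.json",
}
# accepted aliases for the packaged resources
_RESOURCE_ALIASES = {"published_tables": "reference_tables", "modified": "modified_polynomials"}


def _read_resource(filename: str) -> list[dict]:
    path = _importlib_resources.files("dentage.data").joinpath(filename)
    with path.open("r", encoding="utf-8") as fh:
        payload = json.load(fh)
    if not isinstance(payload, list):
        raise ValueError(f"corrupted resource {filename}: expected a JSON list")
    return payload


def _score_table_from_dict(obj: dict) -> ScoreTable:
    entries = {}
    for cell in obj["entries"]:
        key = (int(cell["tooth"]), normalize_stage(cell["stage"]))
        entries[key] = float(cell["score"])
    return ScoreTable(
        system=obj["system"],
        sex=normalize_sex(obj["sex"]),
        entries=entries,
        provenance=obj.get("provenance", ""),
    )


def _polynomial_from_dict(obj: dict) -> PolynomialModel:
    return PolynomialModel(
        sex=normalize_sex(obj["sex"]),
        coefficients=tuple(float(c) for c in obj["coefficients"]),
        score_domain=(float(obj["score_domain"][0]), float(obj["score_domain"][1])),
        provenance=obj.get("provenance", ""),
    )


def _conversion_table_from_dict(obj: dict) -> ConversionTable:
    rows = tuple(
        TableRow(
            age=float(r["age"]),
            score=float(r["score"]),
            flagged=bool(r.get("flagged", False)),
            note=r.get("note", ""),
        )
        for r in obj["rows"]
    )
    return ConversionTable(sex=normalize_sex(obj["sex"]), rows=rows,
                           provenance=obj.get("provenance", ""))


def load_builtin(system: str) -> dict[str, ScoreTable | PolynomialModel | ConversionTable]:
    """Load a packaged resource, keyed by sex code.

    ``system`` is one of ``"demirjian"``, ``"willems"``,
    ``"modified_polynomials"``, ``"reference_tables"`` (the published
    score/age lookup tables, with garbled cells flagged) or
    ``"demirjian_conversion"`` (a synthetic stand-in score->age curve for the
    classical comparison arm).

    Score tables are structurally validated on load; the packaged polynomial
    coefficients are stored digit-for-digit as published.
    """
    name = _RESOURCE_ALIASES.get(system, system)
    if name not in _RESOURCE_FILES:
        known = ", ".join(sorted(_RESOURCE_FILES))
        raise KeyError(f"unknown builtin resource {system!r}; expected one of: {known}")
    payload = _read_resource(_RESOURCE_FILES[name])
    out: dict[str, ScoreTable | PolynomialModel | ConversionTable] = {}
    for obj in payload:
        if name in ("demirjian", "willems"):
            table = _score_table_from_dict(obj)
            report = validate_score_table(table)
            if report.monotonicity_violations or report.missing_cells or report.negative_scores:
                raise ValueError(
                    f"corrupted packaged score table {name}/{table.sex}: "
                    f"{report.monotonicity_violations or report.missing_cells or report.negative_scores}"
                )
            out[table.sex] = table
        elif name == "modified_polynomials":
            model = _polynomial_from_dict(obj)
            out[model.sex] = model
        else:
            table = _conversion_table_from_dict(obj)
            out[table.sex] = table
    if set(out) != set(SEXES):
        raise ValueError(f"corrupted resource {name}: expected one table per sex, got {sorted(out)}")
    return out
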