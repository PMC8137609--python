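"""Maturity score <-> dental age conversion.

The packaged sex-specific quintics map a seven-tooth maturity score ``x`` to
age ``p(x)`` (Horner evaluation).  The inverse direction -- the score a given
age corresponds to -- is obtained by bisection on the score domain, which is
what generates the 0.1-year lookup tables.  A :class:`ConversionTable` can
also be used directly with piecewise-linear interpolation, which is how the
published tables (and the classical comparison curve) are applied to new
subjects.

Out-of-domain policy is explicit everywhere: the default is to raise
:class:`DomainError`; passing ``clamp=True`` (or ``out_of_range="clamp"``)
pins the result at the nearest domain edge instead.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .reference_data import ConversionTable, PolynomialModel, TableRow

__all__ = [
    "AgeGrid",
    "DomainError",
    "evaluate_polynomial",
    "evaluate_polynomial_naive",
    "invert_polynomial",
    "polynomial_is_increasing",
    "build_conversion_table",
    "table_lookup_age",
    "conversion_table_to_frame",
    "conversion_table_to_csv",
    "conversion_table_from_csv",
    "conversion_table_to_text",
]


class DomainError(ValueError):
    """Requested score or age falls outside the model's validity domain."""


@dataclass(frozen=True)
class AgeGrid:
    """Evenly spaced age grid (years, reported to one decimal).

    The default 5.1..16.9 in 0.1-y steps is the layout of the published
    lookup tables (119 rows).
    """

    start: float = 5.1
    stop: float = 16.9
    step: float = 0.1

    def __post_init__(self) -> None:
        if not (self.start <= self.stop and self.step > 0):
            raise ValueError(f"invalid age grid {self}")

    def ages(self) -> tuple[float, ...]:
        # integer stepping avoids float accumulation on the 0.1-y grid
        n = int(round((self.stop - self.start) / self.step))
        return tuple(round(self.start + i * self.step, 1) for i in range(n + 1))


def evaluate_polynomial(model: PolynomialModel, score: float, *, clamp: bool = False) -> float:
    """Dental age ``p(score)`` by Horner's scheme.

    ``score`` must lie in ``model.score_domain`` unless ``clamp=True``, in
    which case it is pinned to the nearest domain edge first.
    """
    lo, hi = model.score_domain
    x = float(score)
    if x < lo or x > hi:
        if not clamp:
            raise DomainError(
                f"score {score} outside domain [{lo}, {hi}] for sex {model.sex}"
            )
        x = min(max(x, lo), hi)
    acc = 0.0
    for c in model.coefficients:
        acc = acc * x + c
    return acc


def evaluate_polynomial_naive(model: PolynomialModel, score: float) -> float:
    """Naive power-sum evaluation; numerical cross-check for Horner."""
    n = model.degree
    x = float(score)
    return float(sum(c * x ** (n - k) for k, c in enumerate(model.coefficients)))


def polynomial_is_increasing(model: PolynomialModel, *, step: float = 0.01) -> bool:
    """Strict monotonicity of ``p`` on its score domain, by a dense scan."""
    lo, hi = model.score_domain
    grid = np.arange(lo, hi + step / 2, step)
    values = np.polyval(model.coefficients, grid)
    return bool(np.all(np.diff(values) > 0))


def invert_polynomial(
    model: PolynomialModel,
    age: float,
    *,
    clamp: bool = False,
    tol: float = 1e-9,
    max_iter: int = 200,
) -> float:
    """Score ``s`` with ``p(s) = age``, by bisection on the score domain.

    Requires ``p(s_min) <= age <= p(s_max)`` (or ``clamp=True`` to pin
    out-of-range ages to the corresponding domain edge).  For a strictly
    increasing model the root is unique; where the model is locally
    non-monotone (the packaged girls quintic dips slightly around scores
    46-56) bisection still converges deterministically to a true root, so
    ``p(invert(age)) == age`` always holds, while ``invert(p(s)) == s`` is
    only guaranteed on strictly increasing stretches.
    """
    lo, hi = model.score_domain
    f_lo = evaluate_polynomial(model, lo) - age
    f_hi = evaluate_polynomial(model, hi) - age
    if f_lo > 0 or f_hi < 0:
        if clamp:
            return lo if f_lo > 0 else hi
        raise DomainError(
            f"age {age} outside achievable range "
            f"[{evaluate_polynomial(model, lo):.4f}, {evaluate_polynomial(model, hi):.4f}] "
            f"for sex {model.sex}"
        )
    if f_lo == 0:
        return lo
    if f_hi == 0:
        return hi
    a, b = lo, hi
    mid = 0.5 * (a + b)
    for _ in range(max_iter):
        mid = 0.5 * (a + b)
        f_mid = evaluate_polynomial(model, mid) - age
        if abs(f_mid) <= tol and (b - a) <= 1e-10:
            return mid
        if f_mid < 0:
            a = mid
        else:
            b = mid
        if b - a < 1e-14:
            break
    return mid


def build_conversion_table(
    model: PolynomialModel,
    grid: AgeGrid | None = None,
    *,
    clamp: bool = False,
) -> ConversionTable:
    """Tabulate the inverse polynomial on an age grid (scores to 2 decimals).

    With ``clamp=False`` every grid age must be achievable; with
    ``clamp=True`` ages beyond the achievable range are pinned to the domain
    edge (needed to cover the full default grid with the packaged girls
    model, whose curve starts at 5.52 y).
    """
    grid = grid or AgeGrid()
    rows = tuple(
        TableRow(age=a, score=round(invert_polynomial(model, a, clamp=clamp), 2))
        for a in grid.ages()
    )
    return ConversionTable(
        sex=model.sex,
        rows=rows,
        provenance=f"generated by inverting a degree-{model.degree} model ({model.provenance})",
    )


def table_lookup_age(
    table: ConversionTable,
    score: float,
    *,
    out_of_range: str = "error",
) -> float:
    """Dental age for a maturity score by linear interpolation in the table.

    Exact row scores return the exact row age.  Scores outside the tabulated
    span either raise (default) or clamp to the boundary age
    (``out_of_range="clamp"``).  Flagged (garbled) rows are ignored.
    """
    rows = table.active_rows()
    scores = np.array([r.score for r in rows])
    ages = np.array([r.age for r in rows])
    order = np.argsort(scores, kind="stable")
    scores, ages = scores[order], ages[order]
    if score < scores[0] or score > scores[-1]:
        if out_of_range == "clamp":
            return float(ages[0] if score < scores[0] else ages[-1])
        raise DomainError(
            f"score {score} outside tabulated range [{scores[0]}, {scores[-1]}]"
        )
    return float(np.interp(score, scores, ages))


# ---------------------------------------------------------------------------
# serialization

def conversion_table_to_frame(table: ConversionTable):
    import pandas as pd

    return pd.DataFrame(
        {
            "age": [r.age for r in table.rows],
            "score": [r.score for r in table.rows],
            "flagged": [r.flagged for r in table.rows],
            "note": [r.note for r in table.rows],
        }
    )


def conversion_table_to_csv(table: ConversionTable, path, *, header_comment: str | None = None) -> None:
    frame = conversion_table_to_frame(table)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def conversion_table_from_csv(path, *, sex: str) -> ConversionTable:
    import pandas as pd

    frame = pd.read_csv(path, comment="#")
    rows = tuple(
        TableRow(
            age=float(r.age),
            score=float(r.score),
            flagged=bool(getattr(r, "flagged", False)),
            note=str(getattr(r, "note", "") or ""),
        )
        for r in frame.itertuples()
    )
    return ConversionTable(sex=sex, rows=rows, provenance=f"read from {path}")


def conversion_table_to_text(table: ConversionTable, *, columns: int = 3) -> str:
    """Pretty-print the table in the familiar multi-column layout."""
    rows = table.rows
    per_col = -(-len(rows) // columns)
    blocks = [rows[i * per_col:(i + 1) * per_col] for i in range(columns)]
    lines = ["  ".join(["Age   Score "] * len(blocks))]
    for i in range(per_col):
        cells = []
        for block in blocks:
            if i < len(block):
                r = block[i]
                mark = "*" if r.flagged else " "
                cells.append(f"{r.age:4.1f} {r.score:7.2f}{mark}")
            else:
                cells.append(" " * 13)
        lines.append("  ".join(cells))
    if any(r.flagged for r in rows):
        lines.append("* flagged transcription artefact (see table notes)")
    return "\n".join(lines)
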