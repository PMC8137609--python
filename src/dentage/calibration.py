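"""Population-specific refitting of the score-to-age polynomial.

Given (maturity score, chronological age) pairs from a new population, an
unweighted least-squares polynomial of age on score is fitted.  A raw
Vandermonde design in scores near 100 is catastrophically ill-conditioned at
degree 5, so the fit is carried out on a centered/scaled score variable
(numpy's mapped-domain polynomial basis) and the coefficients are converted
back to the raw power basis for reporting, making them directly comparable
with published coefficient sets.

Monotonicity of the fitted curve over the sample's score range is checked
and *reported*, never constrained -- the fit is deliberately unconstrained,
which is also why a published curve of this family can contain a shallow
non-monotone dip.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .conversion import polynomial_is_increasing
from .reference_data import PolynomialModel, normalize_sex

__all__ = [
    "CalibrationSample",
    "FitReport",
    "DegreeSelection",
    "fit_polynomial",
    "select_degree",
]

_SCORE_BOUNDS = (0.0, 101.0)
_AGE_BOUNDS = (3.0, 18.0)


@dataclass
class CalibrationSample:
    """Paired (score, age) observations for one sex."""

    scores: np.ndarray
    ages: np.ndarray
    sex: str

    def __post_init__(self) -> None:
        self.scores = np.asarray(self.scores, dtype=float)
        self.ages = np.asarray(self.ages, dtype=float)
        self.sex = normalize_sex(self.sex)
        if self.scores.shape != self.ages.shape or self.scores.ndim != 1:
            raise ValueError("scores and ages must be 1-D arrays of equal length")
        if len(self.scores) < 2:
            raise ValueError("a calibration sample needs at least two pairs")
        lo, hi = _SCORE_BOUNDS
        if np.any(self.scores < lo) or np.any(self.scores > hi):
            raise ValueError(f"scores must lie within [{lo}, {hi}]")
        lo, hi = _AGE_BOUNDS
        if np.any(self.ages < lo) or np.any(self.ages > hi):
            raise ValueError(f"ages must lie within [{lo}, {hi}]")

    def __len__(self) -> int:
        return len(self.scores)

    @classmethod
    def from_records(cls, records: Iterable, sex: str, *, exclude_clamped: bool = True
                     ) -> "CalibrationSample":
        """Build a sample from records carrying both CA and a maturity score.

        Synthetic records whose true score was truncated at a model-domain
        edge (``score_clamped``) no longer lie on the generating curve and
        are excluded by default.
        """
        sex = normalize_sex(sex)
        scores, ages = [], []
        for r in records:
            if r.sex != sex or r.maturity_score is None or r.chronological_age is None:
                continue
            if exclude_clamped and getattr(r, "score_clamped", False):
                continue
            scores.append(r.maturity_score)
            ages.append(r.chronological_age)
        return cls(np.array(scores), np.array(ages), sex)


@dataclass
class FitReport:
    """Outcome of one least-squares polynomial fit."""

    model: PolynomialModel
    degree: int
    n: int
    rmse: float
    mae: float
    holdout_mae: float = float("nan")
    condition_warning: bool = False
    monotone_on_sample: bool = True
    cv_folds: int | None = None
    seed: int | None = None

    def to_dict(self) -> dict:
        return {
            "sex": self.model.sex,
            "degree": self.degree,
            "n": self.n,
            "coefficients": list(self.model.coefficients),
            "score_domain": list(self.model.score_domain),
            "rmse": self.rmse,
            "mae": self.mae,
            "holdout_mae": self.holdout_mae,
            "condition_warning": self.condition_warning,
            "monotone_on_sample": self.monotone_on_sample,
        }


def _fit_raw(scores: np.ndarray, ages: np.ndarray, degree: int) -> tuple[tuple[float, ...], bool]:
    """Centered/scaled LSQ fit; returns raw descending coefficients + rank flag."""
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        fitted = np.polynomial.Polynomial.fit(scores, ages, degree)
    rank_deficient = any(issubclass(w.category, np.exceptions.RankWarning) for w in caught)
    raw_ascending = fitted.convert().coef
    # convert() may drop trailing zero terms; pad back to full length
    if len(raw_ascending) < degree + 1:
        raw_ascending = np.concatenate([raw_ascending, np.zeros(degree + 1 - len(raw_ascending))])
    return tuple(raw_ascending[::-1]), rank_deficient


def fit_polynomial(
    sample: CalibrationSample,
    degree: int = 5,
    *,
    holdout_folds: int | None = None,
    seed: int = 0,
) -> FitReport:
    """Least-squares fit of ``age = p(score)`` at the given degree.

    The default degree is 5, the degree of the packaged reference models.
    Requires at least ``degree + 2`` pairs.  ``holdout_folds`` optionally adds
    a cross-validated MAE to the report (deterministic given ``seed``).
    """
    if degree < 1:
        raise ValueError("degree must be >= 1")
    if len(sample) < degree + 2:
        raise ValueError(
            f"need at least degree + 2 = {degree + 2} pairs, got {len(sample)}"
        )
    coeffs, rank_deficient = _fit_raw(sample.scores, sample.ages, degree)
    model = PolynomialModel(
        sex=sample.sex,
        coefficients=coeffs,
        score_domain=(float(sample.scores.min()), float(sample.scores.max())),
        provenance=f"degree-{degree} least-squares refit on n={len(sample)} pairs",
    )
    predicted = np.polyval(coeffs, sample.scores)
    residuals = sample.ages - predicted
    report = FitReport(
        model=model,
        degree=degree,
        n=len(sample),
        rmse=float(np.sqrt(np.mean(residuals**2))),
        mae=float(np.mean(np.abs(residuals))),
        condition_warning=rank_deficient,
        monotone_on_sample=polynomial_is_increasing(model),
        seed=seed,
    )
    if holdout_folds is not None:
        report.holdout_mae = _cv_mae(sample, degree, holdout_folds, seed)
        report.cv_folds = holdout_folds
    return report


def _cv_mae(sample: CalibrationSample, degree: int, folds: int, seed: int) -> float:
    if folds < 2:
        raise ValueError("cross-validation needs at least 2 folds")
    n = len(sample)
    if n < folds or (n - (-(-n // folds))) < degree + 2:
        raise ValueError(
            f"not enough pairs (n={n}) for {folds}-fold CV at degree {degree}"
        )
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    abs_errors: list[np.ndarray] = []
    for k in range(folds):
        test = order[k::folds]
        train = np.setdiff1d(order, test, assume_unique=True)
        coeffs, _ = _fit_raw(sample.scores[train], sample.ages[train], degree)
        predicted = np.polyval(coeffs, sample.scores[test])
        abs_errors.append(np.abs(sample.ages[test] - predicted))
    return float(np.mean(np.concatenate(abs_errors)))


@dataclass
class DegreeSelection:
    """Cross-validation outcome of :func:`select_degree`."""

    best_degree: int
    cv_mae: dict[int, float] = field(default_factory=dict)
    folds: int = 5
    seed: int = 0


def select_degree(
    sample: CalibrationSample,
    max_degree: int = 7,
    folds: int = 5,
    *,
    seed: int = 0,
) -> DegreeSelection:
    """Pick the polynomial degree by k-fold cross-validated MAE.

    Returns the per-degree CV-MAE table and the degree minimising it; degrees
    whose MAE is within a small relative tolerance of the minimum count as
    ties, which go to the *lower* degree (raising the degree is never
    rewarded for noise-level gains).
    """
    table: dict[int, float] = {}
    for degree in range(1, max_degree + 1):
        table[degree] = _cv_mae(sample, degree, folds, seed)
    best = min(table.values())
    tol = 1e-8 * (1.0 + best)
    chosen = min(d for d, mae in table.items() if mae <= best + tol)
    return DegreeSelection(best_degree=chosen, cv_mae=table, folds=folds, seed=seed)
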