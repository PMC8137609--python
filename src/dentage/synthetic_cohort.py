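"""Synthetic cohorts with the reference study's structure.

No radiograph data are deposited for the reference population, so every
downstream module is exercised on generated cohorts instead.  The generator
emulates what that study reports about its sample:

* twelve one-year age bands (5-16 y) per sex with the published group counts
  (defaults total 2367 records: 1217 boys, 1150 girls),
* chronological age uniform within each band (the published group-mean ages
  sit near mid-interval),
* the score-age relationship given by the packaged sex-specific quintics:
  the *true* maturity score is the model inverse of CA, clamped to the score
  domain, and the *observed* score adds Gaussian rating/developmental noise
  (rejection-truncated to the domain, so no probability mass piles up at the
  edges).

What it deliberately does not emulate: secular trends, ethnicity effects,
per-tooth stage-age distributions, or the unknown real dispersion of score
at fixed age (the noise SD is a free parameter).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np

from .conversion import evaluate_polynomial, invert_polynomial
from .reference_data import (
    FEMALE,
    MALE,
    STAGES,
    TEETH,
    PolynomialModel,
    ScoreTable,
    load_builtin,
)
from .scoring import DentalRecord

__all__ = ["DEFAULT_GROUP_COUNTS", "CohortConfig", "generate_cohort", "emit_stages"]

#: Published cohort composition: (sex, one-year age band) -> count.
DEFAULT_GROUP_COUNTS: Mapping[tuple[str, int], int] = {
    (MALE, 5): 40, (MALE, 6): 126, (MALE, 7): 104, (MALE, 8): 101,
    (MALE, 9): 97, (MALE, 10): 108, (MALE, 11): 114, (MALE, 12): 112,
    (MALE, 13): 109, (MALE, 14): 103, (MALE, 15): 109, (MALE, 16): 94,
    (FEMALE, 5): 46, (FEMALE, 6): 102, (FEMALE, 7): 106, (FEMALE, 8): 112,
    (FEMALE, 9): 91, (FEMALE, 10): 112, (FEMALE, 11): 115, (FEMALE, 12): 127,
    (FEMALE, 13): 93, (FEMALE, 14): 97, (FEMALE, 15): 94, (FEMALE, 16): 55,
}


@dataclass
class CohortConfig:
    """Generator configuration.

    ``score_noise_sd`` is the SD of the Gaussian rating/developmental noise
    on the maturity-score axis (points).  The real dispersion is not
    recoverable from published group summaries; the default 0.5 points is a
    mild-noise setting whose age-scale effect grows from ~0.03 y at young
    ages to >1 y near the score ceiling, mirroring the reported pattern of
    larger errors at older ages.
    """

    group_counts: dict[tuple[str, int], int] = field(
        default_factory=lambda: dict(DEFAULT_GROUP_COUNTS)
    )
    score_noise_sd: float = 0.5
    stage_emission: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.score_noise_sd < 0:
            raise ValueError("score_noise_sd must be >= 0")
        for key, n in self.group_counts.items():
            if n < 0:
                raise ValueError(f"negative count for group {key}")

    def total(self) -> int:
        return sum(self.group_counts.values())


def _truncated_noise(rng: np.random.Generator, center: float, sd: float,
                     lo: float, hi: float, max_tries: int = 10000) -> float:
    for _ in range(max_tries):
        value = center + rng.normal(0.0, sd)
        if lo <= value <= hi:
            return value
    raise RuntimeError("truncated-noise rejection sampling did not converge")


def generate_cohort(
    config: CohortConfig | None = None,
    models: Mapping[str, PolynomialModel] | None = None,
) -> list[DentalRecord]:
    """Generate one deterministic synthetic cohort.

    Per subject: CA ~ Uniform[a, a+1) rounded to 2 decimals; true score =
    model inverse of CA, clamped to the score domain (``score_clamped`` is
    set on the record when clamping fired -- such records do not lie on the
    generating curve); observed score = true score + truncated
    Normal(0, score_noise_sd).  With ``stage_emission`` a seven-tooth stage
    vector approximating the observed score is attached as well.  All
    randomness flows from one generator seeded with ``config.seed``.
    """
    config = config or CohortConfig()
    models = models or load_builtin("modified_polynomials")
    tables: Mapping[str, ScoreTable] | None = (
        load_builtin("demirjian") if config.stage_emission else None
    )
    rng = np.random.default_rng(config.seed)
    records: list[DentalRecord] = []
    for (sex, band), n in sorted(config.group_counts.items()):
        if n == 0:
            continue
        model = models[sex]
        lo, hi = model.score_domain
        age_lo = evaluate_polynomial(model, lo)
        age_hi = evaluate_polynomial(model, hi)
        if band + 1 <= age_lo or band >= age_hi:
            raise ValueError(
                f"age band [{band}, {band + 1}) lies outside the achievable "
                f"range [{age_lo:.2f}, {age_hi:.2f}] for sex {sex}"
            )
        ages = np.round(band + rng.uniform(0.0, 1.0, size=n), 2)
        # 2-decimal rounding must not escape the [band, band+1) group
        ages = np.minimum(ages, band + 0.99)
        for i, ca in enumerate(ages):
            clamped = not (age_lo <= ca <= age_hi)
            true_score = invert_polynomial(model, float(ca), clamp=True)
            if config.score_noise_sd > 0:
                observed = _truncated_noise(rng, true_score, config.score_noise_sd, lo, hi)
            else:
                observed = true_score
            stages = None
            if tables is not None:
                target = min(max(observed, 0.0), tables[sex].max_total())
                stages = emit_stages(target, tables[sex])
            records.append(
                DentalRecord(
                    subject_id=f"SYN-{sex}{band:02d}-{i:04d}",
                    sex=sex,
                    chronological_age=float(ca),
                    maturity_score=float(observed),
                    stages=stages,
                    score_clamped=clamped,
                )
            )
    return records


def emit_stages(target, table: ScoreTable) -> dict[int, str]:
    """Seven-tooth stage vector whose score total approximates ``target``.

    Greedy allocation: starting from all teeth at stage 0, repeatedly advance
    the single tooth whose next score-increasing stage step moves the running
    total closest to the target (flat zero-point stages are skipped over),
    stopping when no single advance improves the gap.  The residual
    |achieved - target| is bounded by the largest single stage increment in
    the table.  ``target`` may also be a record carrying a maturity score.
    """
    if isinstance(target, DentalRecord):
        if target.maturity_score is None:
            raise ValueError(f"record {target.subject_id} has no maturity score")
        target = target.maturity_score
    target = float(target)
    if target < 0 or target > table.max_total() + 1e-9:
        raise ValueError(
            f"target score {target} outside achievable range [0, {table.max_total()}]"
        )
    level = {t: 0 for t in TEETH}
    total = sum(table.score(t, STAGES[0]) for t in TEETH)

    def next_advance(tooth: int) -> tuple[int, float] | None:
        """Next stage index with a strictly larger score, and its step size."""
        current = table.score(tooth, STAGES[level[tooth]])
        for j in range(level[tooth] + 1, len(STAGES)):
            step = table.score(tooth, STAGES[j]) - current
            if step > 0:
                return j, step
        return None

    while True:
        best: tuple[int, int] | None = None
        best_gap = abs(target - total)
        for tooth in TEETH:
            advance = next_advance(tooth)
            if advance is None:
                continue
            j, step = advance
            gap = abs(target - (total + step))
            if gap < best_gap - 1e-12:
                best, best_gap = (tooth, j), gap
        if best is None:
            break
        tooth, j = best
        total += table.score(tooth, STAGES[j]) - table.score(tooth, STAGES[level[tooth]])
        level[tooth] = j
    return {t: STAGES[level[t]] for t in TEETH}
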