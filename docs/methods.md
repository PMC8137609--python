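# Methods

## The estimation model

Tooth mineralisation is staged on panoramic radiographs for the seven left
mandibular permanent teeth (FDI 31–37; the third molar is excluded). Each
tooth is rated `0` (no calcification) or `A`–`H` (crown initiation through
apex closure); the stages form a total order. A sex-specific table converts
each (tooth, stage) pair to self-weighted maturity points, and the
seven-tooth sum is the total maturity score *x* ∈ [0, 100]. With all apices
closed the totals are exactly 100.0 (boys) and 98.4 (girls); these nominal
maxima are used to validate any table loaded through the `ScoreTable`
interface. Stages below the first stage tabulated in the source literature
carry zero points — a convention, not a literature fact, needed so that the
youngest subjects (age 5, with several teeth pre-`A`) are scorable.

Dental age is obtained from *x* through a sex-specific quintic
p(x) = p1·x⁵ + … + p6 calibrated by unweighted least squares on an eastern
Chinese reference cohort (2367 children, ages 5–16, twelve one-year age
bands per sex). The packaged coefficient sets are stored digit for digit as
published. Their validity domains are taken as the span of the published
lookup tables: boys [39.92, 99.25], girls [41.82, 100.10] (the girls' upper
bound stretched to cover a published cell at 100.03 that exceeds the nominal
98.4 maximum — the fit is unconstrained, so nothing prevents tabulated
scores above the attainable range). Out-of-domain inputs raise by default;
every user-facing entry point accepts an explicit clamp flag instead, which
pins the input to the nearest domain edge (the practical choice for all-`H`
boys, whose score 100 exceeds the boys' domain).

## Known inconsistencies in the packaged reference material

These were established numerically during development and drive several
deliberately failing acceptance tests; nothing here is a defect of the
implementation, and none of it was "repaired" in the data.

1. **The published coefficients do not regenerate the published lookup
   tables.** Evaluating the packaged quintics at the tabulated scores
   reproduces the tabulated ages only approximately: boys median |error|
   0.044 y but up to 1.83 y at the low-score edge; girls median 0.35 y, up
   to 0.63 y. Refitting age-on-score quintics to the tables leaves residuals
   of 0.32/0.57 y, whereas *score-on-age* quintics reproduce the tables to
   0.031 (boys) and 0.006 (girls) score points: the tables evidently come
   from fits of score on age, which are not the functional inverses of the
   published age-on-score formulas. Both artefacts are packaged as they
   stand; the acceptance tests that assert mutual consistency at ±0.05 fail
   honestly.
2. **The girls quintic is not monotone on its domain.** Its derivative is
   negative on scores [45.96, 55.70] (a 0.39 y dip). Monotonicity is
   therefore a *reported* property (`polynomial_is_increasing`, 0.01-step
   scan), not an enforced invariant. Inversion uses bisection on the domain
   bracket: it always returns a true root (so p(invert(age)) = age to 1e-9),
   but invert(p(s)) = s is guaranteed only on strictly increasing stretches.
3. **The published tables' age grid exceeds both models' reach.** The boys
   curve tops out at p(99.25) = 16.51 y and the girls curve starts at
   p(41.82) = 5.52 y, yet the tables tabulate 5.1–16.9 y for both sexes.
   Regenerating the full 119-row grid therefore requires edge clamping,
   which the `tables` command applies with a warning.
4. **Flagged cells.** Five tabulated cells are obviously garbled in print
   (run-on digits, a dropped digit, the 100.03 anomaly). They are stored
   verbatim with `flagged=True` and a note, and excluded from interpolation
   and from all automated checks.

## Score ↔ age operations

Evaluation uses Horner's scheme; a naive power-sum evaluator is kept as a
numerical cross-check (agreement to 1e-9 relative is asserted). Inversion is
plain bisection (no derivatives, guaranteed on a bracket) run to an interval
below 1e-10 score points and a residual |p(s) − age| ≤ 1e-9 y. Generated
tables report scores to 2 decimals and ages to 1 decimal, matching the
published layout; all internal computation is full precision, with
round-half-even at the reporting step. Table lookup interpolates linearly
between bracketing rows, returns exact row ages at exact row scores, and has
the same error-or-clamp policy at the table edges.

## Recalibration

`fit_polynomial` performs ordinary (unweighted) least squares of age on
score. The score variable is internally centered and scaled (numpy's
mapped-domain polynomial basis) because a raw degree-5 Vandermonde on scores
near 100 is catastrophically ill-conditioned; coefficients are converted
back to the raw power basis for reporting so they are directly comparable
with the published sets. Rank deficiency sets a `condition_warning` rather
than failing. Monotonicity over the sample's score range is checked and
reported, never constrained (matching how the reference curves were fitted).
A fit needs at least degree + 2 pairs. `select_degree` scores degrees 1..max
by k-fold cross-validated MAE (fold assignment from an explicit seed);
degrees within a 1e-8 relative band of the minimum are treated as tied and
the tie goes to the lowest degree, so noise-level differences never justify
extra curvature. Default degree 5, default 5 folds.

## Evaluation statistics

Subjects are grouped per sex into one-year bands [a, a+1) by floor(CA),
matching the reference study's layout; each non-empty band is reported plus
a pooled Total row per sex. Per group: mean (SD) of CA and DA; diff = CA −
DA with sample SD; t = mean/(sd/√n) with two-sided p from Student's t on
n − 1 df; 95% CI = mean ± t₀.₉₇₅,ₙ₋₁·sd/√n; MAE = mean |diff|; and the count
and percentage (1 decimal) of |diff| ≤ 1 y, inclusive at the boundary. No
multiple-testing correction is applied. A zero-variance difference vector
leaves t undefined (NaN) with p = 1 for exact agreement and p = 0 for a
constant non-zero offset, rather than reporting ±∞. Cohen's kappa is the
unweighted chance-corrected agreement over pooled (rating, rating) pairs —
pooling across teeth and subjects is a documented choice, since per-tooth
pooling conventions are rarely stated; the degenerate single-category case
raises instead of returning 0/0.

## Synthetic cohorts

The generator emulates the reference study's structure: the published
per-group counts (defaults total 2367 = 1217 boys + 1150 girls), CA uniform
within each band (published group means sit near mid-interval) rounded to
two decimals, true score = model inverse of CA clamped to the score domain,
observed score = true score + Normal(0, σ) truncated to the domain by
rejection resampling (no probability atom at the edges). Records whose true
score was clamped (boys above 16.51 y, girls below 5.52 y) are marked
`score_clamped`; they do not lie on the generating curve and are excluded
from calibration samples by default. One `numpy` Generator seeded with the
single config seed drives everything, so cohorts are bit-reproducible.

σ defaults to 0.5 maturity points — a mild-noise setting fixed before any
acceptance measurement. Because the age-on-score curve steepens with score,
a constant score-axis σ yields age errors growing from ~0.03 y at age 6 to
more than 1 y near the ceiling, qualitatively matching the reported pattern
of worse agreement at older ages; the real score dispersion at fixed age is
not recoverable from published group summaries, so σ is a free parameter.

Optional stage emission inverts scoring: a greedy allocator advances, one
step at a time, the tooth whose next score-increasing stage brings the
running total closest to the target (flat zero-point stages are skipped),
stopping when no single advance helps. The residual is bounded by the
largest single stage increment (8.0 points for boys, 5.0 for girls); the
bound is asserted over a dense target grid in the tests, not assumed.

What passing tests on these cohorts do **not** show: performance on real
radiographs. The generator has no rater disagreement structure, no per-tooth
stage–age distributions, no secular or population effects, and its noise
model is exactly the one the estimator assumes, so agreement statistics on
synthetic cohorts are upper bounds on real-data performance.

### Parameter recovery

With σ = 0 a degree-5 refit on the default cohort reproduces the generating
curve to ~1e-12 y everywhere (the data lie exactly on a quintic). With
σ = 0.5 the refit tracks the curve to ≲0.1 y where the cohort actually has
data (scores generated by ages 7–15; asserted at a fixed seed), but
deviates by 0.17–0.46 y over the *full* score domain, for structural
reasons independent of the seed: the domains extend below the cohort's age
span (boys scores < 53 correspond to ages < 5; girls below score 51.4 are
unreachable because of bottom clamping), so the fit extrapolates there, and
errors-in-variables smoothing biases the steep top of the curve. The
acceptance test asserting 0.1 y across the whole domain at σ = 0.5 therefore
fails honestly; the attainable interior statement is the separate green
regression test.

## Problem sizes and runtime

All tests and the acceptance script use the default cohort size (2367
records) or smaller; monotonicity scans use 0.01-point grids and curve
comparisons 1000–2000-point grids. The full suite runs in a few seconds on
one CPU; `scripts/acceptance.py` in about one second.

## Limitations

- The Willems-style table and the classical score→age curve are synthetic
  stand-ins (monotone, plausibly scaled), present so the comparison arms of
  the pipeline run end to end; their outputs are not literature values.
- The transcribed maturity-point tables should be re-verified against the
  original publications before any forensic application.
- No regularised, weighted, or monotonicity-constrained fitting; the model
  family is deliberately the unconstrained polynomial used by the reference
  method.
- Image analysis is out of scope: stage ratings are taken as given.
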