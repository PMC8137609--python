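"""Agreement statistics between chronological and dental age.

The evaluation follows the standard comparison protocol for dental-age
methods: subjects are grouped into one-year age bands by the floor of
chronological age (CA), separately per sex, and each group is summarised by
mean (SD) CA and dental age (DA), the paired difference CA - DA with its 95%
confidence interval and two-sided paired Student t test, the mean absolute
error, and the percentage of subjects whose estimate falls within +/- 1 year
of CA (inclusive at the boundary).  Cohen's unweighted kappa quantifies
inter-/intra-examiner agreement of the categorical stage ratings.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import numpy as np
import pandas as pd
from scipy import stats as _stats

from .scoring import DentalRecord

__all__ = [
    "GroupStats",
    "AccuracyRow",
    "GroupResult",
    "EvalReport",
    "diff_stats",
    "accuracy_within",
    "evaluate_cohort",
    "cohens_kappa",
    "report_to_frame",
    "report_to_csv",
    "report_to_text",
]


@dataclass(frozen=True)
class GroupStats:
    """Paired CA/DA summary for one group of subjects.

    ``exact_agreement`` flags a zero-variance difference vector, for which the
    t statistic is undefined (reported as NaN) and p is 1.0 when the constant
    difference is zero, 0.0 otherwise.
    """

    n: int
    mean_ca: float
    sd_ca: float
    mean_da: float
    sd_da: float
    mean_diff: float
    sd_diff: float
    ci_low: float
    ci_high: float
    t_stat: float
    p_value: float
    mae: float
    exact_agreement: bool = False


@dataclass(frozen=True)
class AccuracyRow:
    """Count and percentage of subjects with |CA - DA| <= threshold."""

    n: int
    count_within: int
    pct_within: float
    threshold: float = 1.0


def _sd(values: np.ndarray) -> float:
    return float(np.std(values, ddof=1)) if len(values) > 1 else float("nan")


def diff_stats(ca: Sequence[float], da: Sequence[float]) -> GroupStats:
    """Paired comparison of chronological vs dental age.

    diff = CA - DA elementwise; t = mean(diff) / (sd(diff)/sqrt(n)) with the
    sample SD (n-1 denominator); two-sided p from Student's t with n-1
    degrees of freedom; 95% CI = mean +/- t_{0.975, n-1} * sd / sqrt(n);
    MAE = mean |diff|.  Requires n >= 2 for t/CI (means and MAE are reported
    for n = 1 with NaN dispersion).
    """
    ca_arr = np.asarray(ca, dtype=float)
    da_arr = np.asarray(da, dtype=float)
    if ca_arr.shape != da_arr.shape or ca_arr.ndim != 1:
        raise ValueError("ca and da must be 1-D sequences of equal length")
    if len(ca_arr) == 0:
        raise ValueError("empty input")
    diff = ca_arr - da_arr
    n = len(diff)
    mean_diff = float(np.mean(diff))
    sd_diff = _sd(diff)
    mae = float(np.mean(np.abs(diff)))
    if n < 2 or not math.isfinite(sd_diff):
        return GroupStats(
            n=n, mean_ca=float(np.mean(ca_arr)), sd_ca=_sd(ca_arr),
            mean_da=float(np.mean(da_arr)), sd_da=_sd(da_arr),
            mean_diff=mean_diff, sd_diff=sd_diff,
            ci_low=float("nan"), ci_high=float("nan"),
            t_stat=float("nan"), p_value=float("nan"), mae=mae,
        )
    if sd_diff == 0.0:
        # all pairs share one constant difference: t is undefined
        return GroupStats(
            n=n, mean_ca=float(np.mean(ca_arr)), sd_ca=_sd(ca_arr),
            mean_da=float(np.mean(da_arr)), sd_da=_sd(da_arr),
            mean_diff=mean_diff, sd_diff=0.0,
            ci_low=mean_diff, ci_high=mean_diff,
            t_stat=float("nan"),
            p_value=1.0 if mean_diff == 0.0 else 0.0,
            mae=mae,
            exact_agreement=mean_diff == 0.0,
        )
    se = sd_diff / math.sqrt(n)
    t_stat = mean_diff / se
    p_value = float(2.0 * _stats.t.sf(abs(t_stat), df=n - 1))
    half_width = float(_stats.t.ppf(0.975, df=n - 1)) * se
    return GroupStats(
        n=n, mean_ca=float(np.mean(ca_arr)), sd_ca=_sd(ca_arr),
        mean_da=float(np.mean(da_arr)), sd_da=_sd(da_arr),
        mean_diff=mean_diff, sd_diff=sd_diff,
        ci_low=mean_diff - half_width, ci_high=mean_diff + half_width,
        t_stat=float(t_stat), p_value=p_value, mae=mae,
    )


def accuracy_within(ca: Sequence[float], da: Sequence[float], threshold: float = 1.0) -> AccuracyRow:
    """Share of subjects with |CA - DA| <= threshold (inclusive boundary)."""
    ca_arr = np.asarray(ca, dtype=float)
    da_arr = np.asarray(da, dtype=float)
    if ca_arr.shape != da_arr.shape or ca_arr.ndim != 1:
        raise ValueError("ca and da must be 1-D sequences of equal length")
    if len(ca_arr) == 0:
        raise ValueError("empty input")
    within = int(np.sum(np.abs(ca_arr - da_arr) <= threshold))
    return AccuracyRow(
        n=len(ca_arr),
        count_within=within,
        pct_within=round(100.0 * within / len(ca_arr), 1),
        threshold=threshold,
    )


@dataclass(frozen=True)
class GroupResult:
    """Statistics for one (sex, one-year age band) cell; band None = pooled."""

    sex: str
    age_group: int | None
    stats: GroupStats
    accuracy: AccuracyRow


@dataclass
class EvalReport:
    """Per-group and pooled comparison of an estimator against CA."""

    method: str
    groups: list[GroupResult] = field(default_factory=list)
    totals: list[GroupResult] = field(default_factory=list)
    exclusions: list[tuple[str, str]] = field(default_factory=list)


def evaluate_cohort(
    records: Iterable[DentalRecord],
    estimator: Callable[[DentalRecord], float],
    *,
    method: str = "estimator",
    threshold: float = 1.0,
) -> EvalReport:
    """Apply an estimator to every record and summarise CA - DA per group.

    Groups are [a, a+1) bands by floor(CA), separately per sex, each
    non-empty band reported plus one pooled Total row per sex.  Records the
    estimator cannot handle are excluded with their reason, not fatal.
    """
    per_group: dict[tuple[str, int], list[tuple[float, float]]] = {}
    per_sex: dict[str, list[tuple[float, float]]] = {}
    report = EvalReport(method=method)
    for record in records:
        if record.chronological_age is None:
            report.exclusions.append((record.subject_id, "no chronological age"))
            continue
        try:
            da = float(estimator(record))
        except Exception as exc:  # estimator failures are data, not bugs
            report.exclusions.append((record.subject_id, str(exc)))
            continue
        ca = record.chronological_age
        per_group.setdefault((record.sex, int(math.floor(ca))), []).append((ca, da))
        per_sex.setdefault(record.sex, []).append((ca, da))
    for (sex, band), pairs in sorted(per_group.items()):
        ca_list, da_list = zip(*pairs)
        report.groups.append(
            GroupResult(sex=sex, age_group=band,
                        stats=diff_stats(ca_list, da_list),
                        accuracy=accuracy_within(ca_list, da_list, threshold))
        )
    for sex, pairs in sorted(per_sex.items()):
        ca_list, da_list = zip(*pairs)
        report.totals.append(
            GroupResult(sex=sex, age_group=None,
                        stats=diff_stats(ca_list, da_list),
                        accuracy=accuracy_within(ca_list, da_list, threshold))
        )
    return report


def cohens_kappa(ratings_a: Sequence, ratings_b: Sequence) -> float:
    """Unweighted Cohen's kappa between two categorical rating series.

    kappa = (p_o - p_e) / (1 - p_e) with the chance agreement p_e from the
    product of the two raters' marginal distributions.  Raises on length
    mismatch and on the degenerate single-category case (p_e = 1).
    """
    a = [str(x) for x in ratings_a]
    b = [str(x) for x in ratings_b]
    if len(a) != len(b):
        raise ValueError("rating lists must have equal length")
    if not a:
        raise ValueError("empty rating lists")
    n = len(a)
    categories = sorted(set(a) | set(b))
    index = {c: i for i, c in enumerate(categories)}
    contingency = np.zeros((len(categories), len(categories)))
    for x, y in zip(a, b):
        contingency[index[x], index[y]] += 1
    p_obs = float(np.trace(contingency)) / n
    marg_a = contingency.sum(axis=1) / n
    marg_b = contingency.sum(axis=0) / n
    p_exp = float(np.dot(marg_a, marg_b))
    if abs(1.0 - p_exp) < 1e-12:
        raise ValueError("degenerate ratings: a single category leaves kappa undefined")
    return (p_obs - p_exp) / (1.0 - p_exp)


# ---------------------------------------------------------------------------
# report output

_COLUMNS = [
    "sex", "age_group", "n", "mean_ca", "sd_ca", "mean_da", "sd_da",
    "mean_diff", "sd_diff", "ci95_low", "ci95_high", "t", "p", "mae",
    "n_within", "pct_within",
]


def report_to_frame(report: EvalReport) -> pd.DataFrame:
    rows = []
    for result in list(report.groups) + list(report.totals):
        s, a = result.stats, result.accuracy
        rows.append({
            "sex": result.sex,
            "age_group": "Total" if result.age_group is None else result.age_group,
            "n": s.n,
            "mean_ca": round(s.mean_ca, 2), "sd_ca": round(s.sd_ca, 2),
            "mean_da": round(s.mean_da, 2), "sd_da": round(s.sd_da, 2),
            "mean_diff": round(s.mean_diff, 2), "sd_diff": round(s.sd_diff, 2),
            "ci95_low": round(s.ci_low, 2), "ci95_high": round(s.ci_high, 2),
            "t": round(s.t_stat, 2), "p": s.p_value, "mae": round(s.mae, 2),
            "n_within": a.count_within, "pct_within": a.pct_within,
        })
    return pd.DataFrame(rows, columns=_COLUMNS)


def report_to_csv(report: EvalReport, path, *, header_comment: str | None = None) -> None:
    frame = report_to_frame(report)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        if header_comment:
            fh.write(f"# {header_comment}\n")
        frame.to_csv(fh, index=False)


def _fmt_p(p: float) -> str:
    if not math.isfinite(p):
        return "   -  "
    return "<0.001" if p < 0.001 else f"{p:6.3f}"


def report_to_text(report: EvalReport) -> str:
    """Aligned-text table (Age, Sex, CA, DA, CA-DA, 95% CI, t, p, MAE, %+-1y)."""
    header = (f"{'Age':>5} {'Sex':>3} {'n':>5}  {'CA mean(SD)':>14} {'DA mean(SD)':>14} "
              f"{'CA-DA (SD)':>14} {'95% CI':>16} {'t':>7} {'p':>6} {'MAE':>5} {'%<=1y':>6}")
    lines = [f"method: {report.method}", header, "-" * len(header)]
    for result in list(report.groups) + list(report.totals):
        s, a = result.stats, result.accuracy
        band = "Total" if result.age_group is None else f"{result.age_group}"
        lines.append(
            f"{band:>5} {result.sex:>3} {s.n:>5}  "
            f"{s.mean_ca:6.2f} ({s.sd_ca:4.2f}) {s.mean_da:6.2f} ({s.sd_da:4.2f}) "
            f"{s.mean_diff:6.2f} ({s.sd_diff:4.2f}) "
            f"{s.ci_low:7.2f};{s.ci_high:7.2f} {s.t_stat:7.2f} {_fmt_p(s.p_value)} "
            f"{s.mae:5.2f} {a.pct_within:6.1f}"
        )
    if report.exclusions:
        lines.append(f"excluded records: {len(report.exclusions)}")
    return "\n".join(lines)
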