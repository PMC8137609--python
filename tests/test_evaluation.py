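"""Agreement statistics: paired t, MAE, accuracy within a band, Cohen's kappa."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats as sps

import dentage
from dentage.reference_data import TEETH

float_vectors = st.lists(
    st.floats(min_value=-5.0, max_value=5.0, allow_nan=False), min_size=3, max_size=40
)


def test_identical_pairs_are_exact_agreement():
    ca = [6.1, 7.3, 9.9, 12.0]
    stats = dentage.diff_stats(ca, ca)
    assert stats.mean_diff == 0.0 and stats.mae == 0.0
    assert stats.exact_agreement
    assert math.isnan(stats.t_stat) and stats.p_value == 1.0


def test_symmetric_differences_give_zero_t():
    da = [10.0, 10.0, 10.0, 10.0]
    ca = [10.5, 9.5, 11.0, 9.0]  # diffs 0.5, -0.5, 1.0, -1.0
    stats = dentage.diff_stats(ca, da)
    assert stats.mean_diff == pytest.approx(0.0)
    assert stats.t_stat == pytest.approx(0.0)
    assert stats.p_value == pytest.approx(1.0)
    assert stats.mae == pytest.approx(0.75)


def test_small_sample_t_statistic():
    # diffs 1, 2, 3: mean 2, sd 1, t = 2/(1/sqrt(3)) = 3.464
    stats = dentage.diff_stats([11.0, 12.0, 13.0], [10.0, 10.0, 10.0])
    assert stats.mean_diff == pytest.approx(2.0)
    assert stats.sd_diff == pytest.approx(1.0)
    assert stats.t_stat == pytest.approx(2.0 * math.sqrt(3), rel=1e-12)
    assert stats.p_value == pytest.approx(2 * sps.t.sf(2.0 * math.sqrt(3), df=2), rel=1e-12)


@given(diffs=float_vectors)
def test_diff_stats_matches_scipy_paired_t(diffs):
    ca = np.asarray(diffs) + 10.0
    da = np.full(len(diffs), 10.0)
    stats = dentage.diff_stats(ca, da)
    assert stats.mae >= abs(stats.mean_diff) - 1e-12
    if stats.sd_diff == 0 or not math.isfinite(stats.sd_diff):
        return
    t_ref, p_ref = sps.ttest_rel(ca, da)
    assert stats.t_stat == pytest.approx(float(t_ref), rel=1e-9, abs=1e-9)
    assert stats.p_value == pytest.approx(float(p_ref), rel=1e-9, abs=1e-9)
    ci = sps.ttest_rel(ca, da).confidence_interval(0.95)
    assert stats.ci_low == pytest.approx(float(ci.low), rel=1e-9, abs=1e-9)
    assert stats.ci_high == pytest.approx(float(ci.high), rel=1e-9, abs=1e-9)
    assert stats.ci_low <= stats.mean_diff <= stats.ci_high


def test_diff_stats_rejects_mismatched_or_empty():
    with pytest.raises(ValueError):
        dentage.diff_stats([1.0, 2.0], [1.0])
    with pytest.raises(ValueError):
        dentage.diff_stats([], [])


def test_accuracy_boundary_is_inclusive():
    row = dentage.accuracy_within([6.5, 7.0, 8.5], [6.0, 6.0, 7.0])  # |diff| 0.5, 1.0, 1.5
    assert row.count_within == 2
    assert row.pct_within == 66.7


@pytest.mark.parametrize(
    "diff,expected", [(0.0, 100.0), (2.0, 0.0)]
)
def test_accuracy_extremes(diff, expected):
    ca = [8.0, 9.0, 10.0]
    da = [v - diff for v in ca]
    assert dentage.accuracy_within(ca, da).pct_within == expected


@given(diffs=float_vectors, t1=st.floats(0.1, 3.0), t2=st.floats(0.1, 3.0))
def test_accuracy_monotone_in_threshold(diffs, t1, t2):
    ca = np.asarray(diffs) + 10.0
    da = np.full(len(diffs), 10.0)
    lo, hi = sorted((t1, t2))
    assert (dentage.accuracy_within(ca, da, lo).count_within
            <= dentage.accuracy_within(ca, da, hi).count_within)


# --- Cohen's kappa ---------------------------------------------------------

def test_kappa_perfect_agreement():
    ratings = ["A", "B", "C", "A", "B"]
    assert dentage.cohens_kappa(ratings, ratings) == pytest.approx(1.0)


def test_kappa_two_by_two_hand_value():
    # contingency a=20 (D,D), b=5 (D,E), c=10 (E,D), d=15 (E,E):
    # p_o = 35/50 = 0.7, p_e = 0.5, kappa = 0.4
    a = ["D"] * 25 + ["E"] * 25
    b = ["D"] * 20 + ["E"] * 5 + ["D"] * 10 + ["E"] * 15
    assert dentage.cohens_kappa(a, b) == pytest.approx(0.4, abs=1e-12)


def test_kappa_independent_ratings_near_zero():
    rng = np.random.default_rng(0)
    cats = list("ABCDEFGH")
    a = rng.choice(cats, 10000)
    b = rng.choice(cats, 10000)
    assert abs(dentage.cohens_kappa(a, b)) < 0.05


@given(st.lists(st.tuples(st.sampled_from("ABC"), st.sampled_from("ABC")),
                min_size=4, max_size=60))
def test_kappa_matches_sklearn_and_is_symmetric(pairs):
    a = [x for x, _ in pairs]
    b = [y for _, y in pairs]
    if len(set(a) | set(b)) < 2:
        return
    from sklearn.metrics import cohen_kappa_score

    try:
        ours = dentage.cohens_kappa(a, b)
    except ValueError:
        return  # degenerate p_e = 1
    assert ours == pytest.approx(float(cohen_kappa_score(a, b)), rel=1e-9, abs=1e-9)
    assert ours == pytest.approx(dentage.cohens_kappa(b, a), abs=1e-12)
    relabel = {"A": "Z", "B": "Q", "C": "K"}
    assert ours == pytest.approx(
        dentage.cohens_kappa([relabel[x] for x in a], [relabel[y] for y in b]), abs=1e-12
    )


def test_kappa_degenerate_single_category():
    with pytest.raises(ValueError, match="degenerate"):
        dentage.cohens_kappa(["A"] * 5, ["A"] * 5)
    with pytest.raises(ValueError, match="length"):
        dentage.cohens_kappa(["A", "B"], ["A"])


# --- cohort evaluation ------------------------------------------------------

def _cohort():
    records = []
    for i, (sex, ca) in enumerate(
        [("M", 5.3), ("M", 5.9), ("M", 6.1), ("F", 5.5), ("F", 7.7), ("F", 7.9)]
    ):
        records.append(dentage.DentalRecord(subject_id=f"r{i}", sex=sex,
                                            chronological_age=ca, maturity_score=50.0 + i))
    return records


def test_evaluate_cohort_perfect_estimator_groups_by_floor_age():
    records = _cohort()
    report = dentage.evaluate_cohort(records, lambda r: r.chronological_age, method="oracle")
    assert [(g.sex, g.age_group) for g in report.groups] == [
        ("F", 5), ("F", 7), ("M", 5), ("M", 6)]
    for group in report.groups + report.totals:
        assert group.stats.mean_diff == 0.0
        assert group.stats.mae == 0.0
        assert group.accuracy.pct_within == 100.0
    assert [t.sex for t in report.totals] == ["F", "M"]
    assert sum(t.stats.n for t in report.totals) == len(records)


def test_evaluate_cohort_logs_estimator_failures():
    records = _cohort()

    def estimator(record):
        if record.subject_id == "r2":
            raise ValueError("stage not defined")
        return record.chronological_age

    report = dentage.evaluate_cohort(records, estimator)
    assert report.exclusions == [("r2", "stage not defined")]
    assert sum(t.stats.n for t in report.totals) == len(records) - 1


def test_evaluate_cohort_mae_dominates_bias(models):
    cohort = dentage.generate_cohort(dentage.CohortConfig(seed=5, score_noise_sd=1.0))
    estimator = lambda r: dentage.evaluate_polynomial(models[r.sex], r.maturity_score, clamp=True)
    report = dentage.evaluate_cohort(cohort, estimator)
    assert report.groups, "cohort must produce groups"
    for group in report.groups + report.totals:
        assert group.stats.mae >= abs(group.stats.mean_diff) - 1e-12
        assert group.accuracy.n == group.stats.n


def test_report_frame_and_text(models):
    records = _cohort()
    report = dentage.evaluate_cohort(records, lambda r: r.chronological_age, method="oracle")
    frame = dentage.report_to_frame(report)
    assert list(frame["age_group"])[-2:] == ["Total", "Total"]
    assert set(frame["sex"]) == {"M", "F"}
    text = dentage.report_to_text(report)
    assert "method: oracle" in text and "Total" in text


def test_report_csv_round_trip(tmp_path):
    import pandas as pd

    report = dentage.evaluate_cohort(_cohort(), lambda r: r.chronological_age)
    path = tmp_path / "report.csv"
    dentage.report_to_csv(report, path, header_comment="check")
    frame = pd.read_csv(path, comment="#")
    assert len(frame) == len(report.groups) + len(report.totals)
    assert frame["n"].sum() == 2 * sum(t.stats.n for t in report.totals)
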