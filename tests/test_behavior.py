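"""Dependent measures from trial logs: accuracy, perseveration, RTs, touches."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from ratcat.behavior import (
    correct_side,
    count_perseverative_errors,
    filter_rt_outliers,
    session_accuracy,
    summarize_sessions,
    third_touch_separation,
    touch_separation,
)


def make_log(rows):
    """rows: (trial, is_correction, response, correct) for one subject-session."""
    df = pd.DataFrame(rows, columns=["trial", "is_correction", "response", "correct"])
    df["subject_id"] = "s1"
    df["session"] = 1
    return df


def test_category_to_side_mapping():
    assert list(correct_side(["A", "B"])) == ["left", "right"]


class TestSessionAccuracy:
    def test_simple_ratio(self):
        rows = [(t, False, "left", t < 60) for t in range(80)]
        assert session_accuracy(make_log(rows)) == pytest.approx(60 / 80)

    def test_correction_rows_excluded_from_denominator(self):
        # 80 first attempts (40 correct) plus 55 correction rows
        rows = [(t, False, "left", t < 40) for t in range(80)]
        rows += [(79, True, "left", False) for _ in range(55)]
        assert session_accuracy(make_log(rows)) == pytest.approx(0.5)

    def test_all_correct(self):
        rows = [(t, False, "left", True) for t in range(10)]
        assert session_accuracy(make_log(rows)) == 1.0

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            session_accuracy(make_log([(0, True, "left", False)]))


@pytest.mark.parametrize(
    "attempts, expected",
    [
        # error(left) -> correction error(left) -> correction correct(right)
        ([("left", False, False), ("left", False, True), ("right", True, True)], 1),
        # error(left) -> correction correct(right)
        ([("left", False, False), ("right", True, True)], 0),
        # two repeated errors before switching
        ([("left", False, False), ("left", False, True), ("left", False, True),
          ("right", True, True)], 2),
    ],
)
def test_perseverative_error_counts(attempts, expected):
    rows = [(0, is_corr, resp, ok) for resp, ok, is_corr in attempts]
    assert count_perseverative_errors(make_log(rows)) == expected


class TestRTFilter:
    def test_removes_far_outlier(self):
        rts = np.array([1.0] * 19 + [10.0])
        kept, warned = filter_rt_outliers(rts, np.ones(20, dtype=bool))
        assert not warned
        assert 10.0 not in kept and len(kept) == 19

    def test_zero_sd_keeps_everything(self):
        kept, warned = filter_rt_outliers([2.0] * 5, [True] * 5)
        assert list(kept) == [2.0] * 5 and not warned

    def test_values_within_two_sd_untouched(self):
        rts = np.array([1.0, 1.2, 0.8, 1.1, 0.9])
        kept, _ = filter_rt_outliers(rts, np.ones(5, dtype=bool))
        assert np.allclose(np.sort(kept), np.sort(rts))

    def test_incorrect_trials_dropped_first(self):
        rts = np.array([1.0, 1.1, 0.9, 50.0])
        kept, _ = filter_rt_outliers(rts, [True, True, True, False])
        assert np.allclose(np.sort(kept), [0.9, 1.0, 1.1])

    def test_fewer_than_three_warns(self):
        with pytest.warns(UserWarning):
            kept, warned = filter_rt_outliers([1.0, 2.0], [True, True])
        assert warned and len(kept) == 2


class TestTouchSeparation:
    def test_third_touch_toward_correct_right(self):
        sep = touch_separation([100.0, 110.0, 120.0], "right")
        assert sep[2] == pytest.approx(10.0)

    def test_sign_flips_for_left(self):
        sep = touch_separation([100.0, 110.0, 120.0], "left")
        assert sep[2] == pytest.approx(-10.0)

    def test_equal_touches_zero(self):
        assert np.allclose(touch_separation([200.0] * 3, "right"), 0.0)

    def test_missing_touch_rejected(self):
        with pytest.raises(ValueError):
            touch_separation([100.0, np.nan, 120.0], "right")

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.floats(-1e4, 1e4), min_size=3, max_size=3),
           st.sampled_from(["left", "right"]))
    def test_mean_centering_identity(self, touches, side):
        assert abs(touch_separation(touches, side).sum()) < 1e-6


def full_log():
    rng = np.random.default_rng(0)
    rows = []
    for subj in ("a", "b"):
        for session in (1, 2):
            for trial in range(20):
                correct = bool(rng.random() < 0.7)
                cat = "A" if rng.random() < 0.5 else "B"
                resp = ("left" if cat == "A" else "right") if correct else \
                       ("right" if cat == "A" else "left")
                rows.append((subj, "control", 0, session, trial, False, 30.0, 50.0,
                             cat, resp, correct, rng.lognormal(0.5, 0.3),
                             rng.lognormal(0, 0.3), *rng.normal(320, 15, 3)))
                if not correct:
                    rows.append((subj, "control", 0, session, trial, True, 30.0, 50.0,
                                 cat, "left" if resp == "right" else "right", True,
                                 rng.lognormal(0.5, 0.3), rng.lognormal(0, 0.3),
                                 *rng.normal(320, 15, 3)))
    return pd.DataFrame(rows, columns=[
        "subject_id", "group", "rotation_deg", "session", "trial", "is_correction",
        "x_norm", "y_norm", "category", "response", "correct",
        "cue_rt", "choice_rt", "touch_x1", "touch_x2", "touch_x3"])


def test_summary_invariant_to_subject_and_column_order():
    log = full_log()
    base = summarize_sessions(log)
    # reorder subject blocks (within-trial attempt order preserved) and columns
    reordered = pd.concat([log[log.subject_id == "b"], log[log.subject_id == "a"]])
    reordered = reordered[list(reversed(log.columns))]
    alt = summarize_sessions(reordered)
    key = ["subject_id", "session"]
    pd.testing.assert_frame_equal(
        base.sort_values(key).reset_index(drop=True)[base.columns],
        alt.sort_values(key).reset_index(drop=True)[base.columns],
    )


def test_summary_counts_and_accuracy_consistent():
    log = full_log()
    out = summarize_sessions(log)
    one = log[(log.subject_id == "a") & (log.session == 1)]
    row = out[(out.subject_id == "a") & (out.session == 1)].iloc[0]
    assert row["accuracy"] == pytest.approx(session_accuracy(one))
    assert row["n_corrections"] == int(one.is_correction.sum())


def test_cohort_dissociation_direction(cohort):
    """Synthetic cohorts show the lesion deficit on 1D tasks, not on 2D.

    The deficit concentrates in early training (both groups converge by the
    final sessions), so the contrast uses the first five sessions."""
    from scipy import stats

    summary = summarize_sessions(
        cohort.trials[cohort.trials.session <= 5])
    summary["task_class"] = np.where(summary.rotation_deg.isin([0, 90]), "1D", "2D")
    per_subj = summary.groupby(["group", "task_class", "subject_id"]
                               ).accuracy.mean().reset_index()

    def group_vals(g, tc):
        sel = per_subj[(per_subj.group == g) & (per_subj.task_class == tc)]
        return sel.accuracy.to_numpy()

    t1, p1 = stats.ttest_ind(group_vals("control", "1D"),
                             group_vals("lesion", "1D"), alternative="greater")
    assert p1 < 0.05
    c2, l2 = group_vals("control", "2D"), group_vals("lesion", "2D")
    _, p2 = stats.ttest_ind(c2, l2)
    assert p2 > 0.05 and abs(c2.mean() - l2.mean()) < 0.04
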