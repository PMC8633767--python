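"""Dependent measures from trial-level touchscreen logs.

A trial log is a tidy table with one row per *attempt*: the first attempt
at each trial plus any correction attempts (the same stimulus repeated
after an error until the correct report key is pressed).  Expected columns:

    subject_id, group, rotation_deg, session, trial, is_correction,
    x_norm, y_norm, category, response, correct, cue_rt, choice_rt,
    touch_x1, touch_x2, touch_x3

Category A maps to the left report key, category B to the right.  Rows are
expected in presentation order within each (subject_id, session, trial).

Measures
--------
* session accuracy — proportion of correct *first attempts* (correction
  attempts are a separate measure and are excluded from the denominator);
* correction counts and perseverative errors (same incorrect key pressed
  again immediately after negative feedback, within a correction loop);
* reaction times with incorrect trials dropped and a single-pass 2-SD
  outlier cut per subject and measure;
* touch separation — signed deviation of each Cue-phase touch from the
  trial's mean touch x-coordinate, positive toward the correct side; the
  third touch is the headline value, computed on correct first attempts.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

__all__ = [
    "TRIAL_COLUMNS",
    "correct_side",
    "session_accuracy",
    "count_perseverative_errors",
    "filter_rt_outliers",
    "touch_separation",
    "third_touch_separation",
    "summarize_sessions",
]

TRIAL_COLUMNS = [
    "subject_id", "group", "rotation_deg", "session", "trial", "is_correction",
    "x_norm", "y_norm", "category", "response", "correct",
    "cue_rt", "choice_rt", "touch_x1", "touch_x2", "touch_x3",
]


def correct_side(category) -> np.ndarray:
    """Report key mapped to a category: A -> left, B -> right."""
    return np.where(np.asarray(category) == "A", "left", "right")


def session_accuracy(records: pd.DataFrame) -> float:
    """Proportion of correct responses among first attempts.

    Correction attempts replay a stimulus the subject just got wrong, so
    they are excluded from the accuracy denominator.
    """
    first = records.loc[~records["is_correction"].astype(bool)]
    if len(first) == 0:
        raise ValueError("no non-correction trials in records")
    return float(first["correct"].astype(bool).mean())


def count_perseverative_errors(records: pd.DataFrame) -> int:
    """Repeated incorrect presses of the same key after negative feedback.

    Counted within each trial's correction loop: a correction attempt is
    perseverative when it presses the same (incorrect) report key as the
    immediately preceding failed attempt at the same stimulus.  Rows must be
    in presentation order within each (subject, session, trial).
    """
    n = 0
    for _, grp in records.groupby(["subject_id", "session", "trial"], sort=False):
        resp = grp["response"].to_numpy()
        corr = grp["correct"].astype(bool).to_numpy()
        is_corr = grp["is_correction"].astype(bool).to_numpy()
        for i in range(1, len(grp)):
            if is_corr[i] and not corr[i - 1] and resp[i] == resp[i - 1]:
                n += 1
    return n


def filter_rt_outliers(rts, correct) -> tuple[np.ndarray, bool]:
    """Exclude incorrect-trial RTs, then drop values beyond 2 SD of the mean.

    The mean and SD are computed once over the retained correct-trial values
    (single pass, no re-estimation after removal).  Degenerate cases — fewer
    than 3 correct-trial values, or zero SD — return the correct-trial
    values unfiltered; the former also raises a warning flag.

    Returns ``(filtered_values, warned)``.
    """
    rts = np.asarray(rts, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    if rts.shape != correct.shape:
        raise ValueError("rts and correctness flags must align")
    vals = rts[correct]
    if len(vals) < 3:
        warnings.warn("fewer than 3 correct-trial RTs; returning unfiltered")
        return vals, True
    sd = vals.std(ddof=0)
    if sd == 0.0:
        return vals, False
    keep = np.abs(vals - vals.mean()) <= 2.0 * sd
    return vals[keep], False


def touch_separation(touch_x, side) -> np.ndarray:
    """Signed per-touch deviation from the trial's mean touch x-coordinate.

    ``side`` is the trial's correct side ('left' or 'right'); separations
    are positive toward it (sign +1 for right, -1 for left).  The three
    values of any trial sum to zero by construction.
    """
    touch_x = np.asarray(touch_x, dtype=float)
    if touch_x.shape[-1] != 3 or np.any(~np.isfinite(touch_x)):
        raise ValueError("exactly three finite touch x-coordinates are required")
    s = 1.0 if side == "right" else -1.0
    return s * (touch_x - touch_x.mean(axis=-1, keepdims=True))


def third_touch_separation(records: pd.DataFrame) -> float:
    """Mean third-touch separation over correct first attempts (pixels)."""
    ok = records.loc[
        records["correct"].astype(bool) & ~records["is_correction"].astype(bool)
    ]
    if len(ok) == 0:
        return np.nan
    tx = ok[["touch_x1", "touch_x2", "touch_x3"]].to_numpy(dtype=float)
    sign = np.where(ok["category"].to_numpy() == "A", -1.0, 1.0)
    return float(np.mean(sign * (tx[:, 2] - tx.mean(axis=1))))


def summarize_sessions(log: pd.DataFrame) -> pd.DataFrame:
    """Per subject-session summary table of all dependent measures.

    RT outlier filtering is applied per subject and measure across that
    subject's sessions (correct trials only, single 2-SD pass); session
    means are then computed over the retained attempts.  Training and
    testing phases should be summarized in separate calls so that their RT
    filters do not mix.  Returns one row
    per (subject_id, session) with columns: group, rotation_deg, accuracy,
    n_corrections, n_perseverative, mean_cue_rt, mean_choice_rt,
    mean_touch_separation.
    """
    log = log.copy()
    log["is_correction"] = log["is_correction"].astype(bool)
    log["correct"] = log["correct"].astype(bool)

    keep_masks = {}
    for measure in ("cue_rt", "choice_rt"):
        keep = pd.Series(False, index=log.index)
        for _, grp in log.groupby("subject_id", sort=False):
            ok = grp.loc[grp["correct"]]
            vals = ok[measure].to_numpy(dtype=float)
            if len(vals) < 3 or vals.std(ddof=0) == 0.0:
                keep.loc[ok.index] = True
                continue
            inliers = np.abs(vals - vals.mean()) <= 2.0 * vals.std(ddof=0)
            keep.loc[ok.index[inliers]] = True
        keep_masks[measure] = keep

    rows = []
    for (subj, session), grp in log.groupby(["subject_id", "session"], sort=True):
        first = grp.loc[~grp["is_correction"]]
        rows.append(
            {
                "subject_id": subj,
                "session": session,
                "group": grp["group"].iloc[0],
                "rotation_deg": grp["rotation_deg"].iloc[0],
                "accuracy": float(first["correct"].mean()),
                "n_corrections": int(grp["is_correction"].sum()),
                "n_perseverative": count_perseverative_errors(grp),
                "mean_cue_rt": float(grp.loc[keep_masks["cue_rt"]
                                             .reindex(grp.index, fill_value=False),
                                             "cue_rt"].mean()),
                "mean_choice_rt": float(grp.loc[keep_masks["choice_rt"]
                                                .reindex(grp.index, fill_value=False),
                                                "choice_rt"].mean()),
                "mean_touch_separation": third_touch_separation(grp),
            }
        )
    return pd.DataFrame(rows)
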