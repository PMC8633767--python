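"""Perceptual recency analysis with a shuffled-trial-order permutation null.

Category decisions can be biased toward the most recent training exemplar.
To isolate that trial-order effect, each trial *n* is paired with its
predecessor *n−1* and scored by their perceived similarity

    s(n, n-1) = exp(-d),   d = sum_m w_m |x_nm - x_(n-1)m|,

an attention-weighted city-block distance on the model's [0,1] stimulus
coordinates, with ``w`` the model's normalized attention weights on trial
*n*.  Accuracy is binned by similarity (quantile bins plus a median split),
and each binned accuracy is referenced to the average of the same statistic
over permutations of the trial order: a positive recency score means the
actual ordering helped accuracy in that similarity range, zero means trial
order was irrelevant.

Permutations shuffle whole trials (stimulus, outcome, weights move as a
unit), so marginal accuracy is preserved exactly and only the adjacency
structure is destroyed.  Correction attempts are excluded: they repeat the
same stimulus mechanically and would flood the high-similarity bins.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RecencyConfig",
    "RecencyResult",
    "psychological_distance",
    "perceptual_similarity",
    "trial_weights",
    "pair_similarities",
    "recency_scores",
    "subject_scores_from_logs",
    "group_test",
]


@dataclass(frozen=True)
class RecencyConfig:
    """Permutation-null settings: 1000 order shuffles, 8 quantile bins."""

    n_perm: int = 1000
    n_bins: int = 8
    seed: int | None = None

    def __post_init__(self):
        if self.n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        if self.n_bins < 2:
            raise ValueError("n_bins must be >= 2")


def psychological_distance(x_i, x_j, w) -> float:
    """Attention-weighted city-block distance between two stimuli."""
    w = np.asarray(w, dtype=float)
    if np.any(w < 0):
        raise ValueError("attention weights must be non-negative")
    return float(np.sum(w * np.abs(np.asarray(x_i, float) - np.asarray(x_j, float))))


def perceptual_similarity(d) -> float:
    """Exponential generalization gradient: s = e^(-d), in (0, 1]."""
    d = np.asarray(d, dtype=float)
    if np.any(d < 0):
        raise ValueError("distance must be non-negative")
    out = np.exp(-d)
    return float(out) if out.ndim == 0 else out


def trial_weights(lam_trace: np.ndarray) -> np.ndarray:
    """Normalize per-trial attention weights to sum 1 per trial.

    Rows of all-zero attention fall back to uniform weights.
    """
    lam = np.atleast_2d(np.asarray(lam_trace, dtype=float))
    if np.any(lam < 0):
        raise ValueError("attention weights must be non-negative")
    tot = lam.sum(axis=1, keepdims=True)
    w = np.where(tot > 0, lam / np.where(tot == 0, 1.0, tot), 1.0 / lam.shape[1])
    return w


def pair_similarities(xy: np.ndarray, weights: np.ndarray) -> np.ndarray:
    """Similarity of each trial to its predecessor (length n-1).

    Element ``t`` is s(t+1, t), computed with the weights of the current
    trial ``t+1``.
    """
    xy = np.asarray(xy, dtype=float)
    weights = np.asarray(weights, dtype=float)
    if xy.shape != weights.shape:
        raise ValueError("stimuli and weights must align trial-for-trial")
    d = np.sum(weights[1:] * np.abs(xy[1:] - xy[:-1]), axis=1)
    return np.exp(-d)


@dataclass
class RecencyResult:
    """Observed-minus-permuted accuracy by similarity bin and median split."""

    bin_scores: np.ndarray        # (n_bins,) observed - mean(permuted)
    bin_observed: np.ndarray
    bin_perm_mean: np.ndarray
    bin_perm_sd: np.ndarray
    bin_band: np.ndarray          # (2, n_bins) permutation 2.5/97.5 percentiles of scores
    split_scores: dict            # {"high": ..., "low": ...}
    split_observed: dict
    split_perm_mean: dict
    split_perm_sd: dict
    n_trials: int
    n_perm: int


def _binned_accuracy(s: np.ndarray, acc: np.ndarray, n_bins: int) -> np.ndarray:
    edges = np.quantile(s, np.linspace(0, 1, n_bins + 1)[1:-1])
    idx = np.searchsorted(edges, s, side="right")
    out = np.full(n_bins, np.nan)
    for b in range(n_bins):
        m = idx == b
        if m.any():
            out[b] = acc[m].mean()
    return out


def _split_accuracy(s: np.ndarray, acc: np.ndarray) -> tuple[float, float]:
    med = np.median(s)
    hi = s > med
    lo = ~hi
    return (acc[hi].mean() if hi.any() else np.nan,
            acc[lo].mean() if lo.any() else np.nan)


def recency_scores(
    xy: np.ndarray,
    correct: np.ndarray,
    weights: np.ndarray,
    config: RecencyConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> RecencyResult:
    """Recency scores for one subject's first-attempt training sequence.

    ``xy`` are model-coordinate stimuli (n, 2), ``correct`` binary outcome
    flags, ``weights`` per-trial normalized attention (n, 2).  Quantile bin
    edges and the similarity median are recomputed inside every permutation
    from the permuted sequence.
    """
    cfg = RecencyConfig() if config is None else config
    xy = np.asarray(xy, dtype=float)
    correct = np.asarray(correct, dtype=float)
    n = len(correct)
    if n < 2:
        raise ValueError("need at least two trials")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)

    s_obs = pair_similarities(xy, weights)
    acc_obs = correct[1:]
    bin_obs = _binned_accuracy(s_obs, acc_obs, cfg.n_bins)
    hi_obs, lo_obs = _split_accuracy(s_obs, acc_obs)

    # permutation engine: whole-trial shuffles, vectorized across permutations
    P = np.argsort(rng.random((cfg.n_perm, n)), axis=1)
    cur, prev = P[:, 1:], P[:, :-1]
    d = np.sum(weights[cur] * np.abs(xy[cur] - xy[prev]), axis=2)
    s_perm = np.exp(-d)            # (n_perm, n-1)
    acc_perm = correct[cur]

    bin_perm = np.full((cfg.n_perm, cfg.n_bins), np.nan)
    hi_perm = np.empty(cfg.n_perm)
    lo_perm = np.empty(cfg.n_perm)
    qs = np.linspace(0, 1, cfg.n_bins + 1)[1:-1]
    edges_all = np.quantile(s_perm, qs, axis=1).T   # (n_perm, n_bins-1)
    med_all = np.median(s_perm, axis=1)
    for p in range(cfg.n_perm):
        idx = np.searchsorted(edges_all[p], s_perm[p], side="right")
        a = acc_perm[p]
        for b in range(cfg.n_bins):
            m = idx == b
            if m.any():
                bin_perm[p, b] = a[m].mean()
        hi = s_perm[p] > med_all[p]
        hi_perm[p] = a[hi].mean() if hi.any() else np.nan
        lo_perm[p] = a[~hi].mean() if (~hi).any() else np.nan

    with np.errstate(invalid="ignore"):
        bin_mean = np.nanmean(bin_perm, axis=0)
        bin_sd = np.nanstd(bin_perm, axis=0)
        band = np.nanpercentile(bin_perm, [2.5, 97.5], axis=0) - bin_mean
    return RecencyResult(
        bin_scores=bin_obs - bin_mean,
        bin_observed=bin_obs,
        bin_perm_mean=bin_mean,
        bin_perm_sd=bin_sd,
        bin_band=band,
        split_scores={"high": hi_obs - np.nanmean(hi_perm),
                      "low": lo_obs - np.nanmean(lo_perm)},
        split_observed={"high": hi_obs, "low": lo_obs},
        split_perm_mean={"high": float(np.nanmean(hi_perm)),
                         "low": float(np.nanmean(lo_perm))},
        split_perm_sd={"high": float(np.nanstd(hi_perm)),
                       "low": float(np.nanstd(lo_perm))},
        n_trials=n,
        n_perm=cfg.n_perm,
    )


def subject_scores_from_logs(
    trials: pd.DataFrame,
    traces: pd.DataFrame,
    config: RecencyConfig | None = None,
    rng: np.random.Generator | int | None = None,
) -> pd.DataFrame:
    """Median-split recency scores for every subject in a cohort log.

    ``trials`` is a TrialRecord table (training phase); correction attempts
    are dropped.  ``traces`` is the matching model-trace table providing
    per-trial attention (columns subject_id, session, trial, lambda_x,
    lambda_y), aligned on (subject_id, session, trial).  Returns one row per
    subject x split with the score and its permutation SE.
    """
    cfg = RecencyConfig() if config is None else config
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(cfg.seed if rng is None else rng)
    first = trials.loc[~trials["is_correction"].astype(bool)].copy()
    rows = []
    for subj, grp in first.groupby("subject_id", sort=True):
        grp = grp.sort_values(["session", "trial"])
        tr = traces.loc[traces["subject_id"] == subj].sort_values(["session", "trial"])
        if len(tr) != len(grp):
            raise ValueError(f"trace/log length mismatch for subject {subj}")
        xy = grp[["x_norm", "y_norm"]].to_numpy(dtype=float) / 100.0
        w = trial_weights(tr[["lambda_x", "lambda_y"]].to_numpy(dtype=float))
        res = recency_scores(xy, grp["correct"].to_numpy(dtype=float), w, cfg, rng)
        for split in ("high", "low"):
            rows.append(
                {
                    "subject_id": subj,
                    "group": grp["group"].iloc[0],
                    "split": split,
                    "score": res.split_scores[split],
                    "perm_sd": res.split_perm_sd[split],
                }
            )
    return pd.DataFrame(rows)


def group_test(scores: pd.DataFrame) -> pd.DataFrame:
    """One-sample t-tests of median-split recency scores against zero.

    One row per group x split with t, p, df, mean and a ``degenerate`` flag
    set when the score variance is zero (t undefined).
    """
    rows = []
    for (group, split), grp in scores.groupby(["group", "split"], sort=True):
        vals = grp["score"].to_numpy(dtype=float)
        degenerate = len(vals) < 2 or np.allclose(vals.std(ddof=1), 0.0)
        if degenerate and not np.allclose(vals, 0.0):
            t, p = np.nan, np.nan
        elif degenerate:
            t, p = 0.0, 1.0
        else:
            t, p = stats.ttest_1samp(vals, 0.0)
        rows.append(
            {
                "group": group, "split": split, "n": len(vals),
                "mean": float(vals.mean()), "t": float(t), "p": float(p),
                "df": len(vals) - 1, "degenerate": bool(degenerate),
            }
        )
    return pd.DataFrame(rows)
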