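"""Gabor stimulus space and rotated bivariate-normal category tasks.

Stimuli are sine gratings varying along two continuous dimensions: spatial
frequency (cycles per visual degree, cpd) and orientation (radians).  Both
dimensions are linearly mapped onto a common 0-100 scale so that a category
task can be written as a pair of bivariate normal distributions on a square
stimulus space.  The base task places category A at (30, 50) and category B
at (70, 50) with SD 2.5 along the axis joining the means (the category
*relevant* axis) and SD 20 along the orthogonal axis; three further tasks
are obtained by rotating both distributions in 45-degree steps about the
centre of the space.  Rotations of 0 and 90 degrees leave the distributions
perpendicular to a stimulus axis, so a single dimension suffices for
classification (1D tasks); 45- and 135-degree rotations make both dimensions
informative (2D tasks).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "FREQ_STEP_CPD",
    "FREQ_OFFSET",
    "ORI_MAX_RAD",
    "Exemplar",
    "CategoryTask",
    "normalize_frequency",
    "denormalize_frequency",
    "normalize_orientation",
    "denormalize_orientation",
    "build_task",
    "sample_exemplars",
    "classify_trial_type",
]

#: slope and offset of the linear map from cpd to normalized units:
#: x_norm = cpd / FREQ_STEP_CPD - FREQ_OFFSET
FREQ_STEP_CPD = 0.0097
FREQ_OFFSET = 26.10
#: upper bound of the raw orientation range (maps to 100.27 normalized units,
#: slightly above 100; the normalized space is the authoritative one).
ORI_MAX_RAD = 1.75

CENTER = np.array([50.0, 50.0])
MEAN_OFFSET = 20.0          # |mean - center| along the relevant axis
SIGMA_RELEVANT_TRAIN = 2.5
SIGMA_RELEVANT_TEST = 10.0
SIGMA_ORTHOGONAL = 20.0
TRAINED_BAND_SD = 2.0       # "Trained" = within 2 training SDs of the mean

ROTATIONS = (0, 45, 90, 135)


def normalize_frequency(freq_cpd):
    """Map spatial frequency (cpd) onto the common 0-100 scale.

    Raises ``ValueError`` for non-positive frequencies.
    """
    freq_cpd = np.asarray(freq_cpd, dtype=float)
    if np.any(freq_cpd <= 0):
        raise ValueError("spatial frequency must be positive (cpd)")
    out = freq_cpd / FREQ_STEP_CPD - FREQ_OFFSET
    return float(out) if out.ndim == 0 else out


def denormalize_frequency(x_norm):
    """Inverse of :func:`normalize_frequency`."""
    x_norm = np.asarray(x_norm, dtype=float)
    out = FREQ_STEP_CPD * (x_norm + FREQ_OFFSET)
    return float(out) if out.ndim == 0 else out


def normalize_orientation(ori_rad):
    """Map orientation (radians, within [0, 1.75]) onto normalized units."""
    ori_rad = np.asarray(ori_rad, dtype=float)
    if np.any(ori_rad < 0) or np.any(ori_rad > ORI_MAX_RAD):
        raise ValueError(f"orientation must lie in [0, {ORI_MAX_RAD}] rad")
    out = ori_rad * 180.0 / np.pi
    return float(out) if out.ndim == 0 else out


def denormalize_orientation(y_norm):
    """Inverse of :func:`normalize_orientation` (no range check)."""
    y_norm = np.asarray(y_norm, dtype=float)
    out = y_norm * np.pi / 180.0
    return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class Exemplar:
    """A single grating stimulus with raw and normalized coordinates."""

    freq_cpd: float
    ori_rad: float
    x_norm: float
    y_norm: float
    category: str  # "A" or "B"

    @classmethod
    def from_normalized(cls, x_norm: float, y_norm: float, category: str) -> "Exemplar":
        return cls(
            freq_cpd=denormalize_frequency(x_norm),
            ori_rad=denormalize_orientation(y_norm),
            x_norm=float(x_norm),
            y_norm=float(y_norm),
            category=category,
        )


def _rotation_matrix(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


@dataclass(frozen=True)
class CategoryTask:
    """A rotation-indexed pair of bivariate normal category distributions.

    ``relevant_axis`` is the unit vector perpendicular to the elongated
    distributions (the rotated x-axis); the category boundary is the line
    through the centre of the space orthogonal to it.
    """

    rotation_deg: int
    mean_A: np.ndarray
    mean_B: np.ndarray
    cov_A: np.ndarray
    cov_B: np.ndarray
    task_class: str          # "1D" or "2D"
    relevant_axis: np.ndarray
    boundary_point: np.ndarray = field(default_factory=lambda: CENTER.copy())

    def mean(self, category: str) -> np.ndarray:
        return self.mean_A if category == "A" else self.mean_B

    def cov(self, phase: str = "train") -> np.ndarray:
        """Covariance for the given phase (testing widens the relevant axis)."""
        sig_rel = SIGMA_RELEVANT_TRAIN if phase == "train" else SIGMA_RELEVANT_TEST
        R = _rotation_matrix(self.rotation_deg)
        return R @ np.diag([sig_rel**2, SIGMA_ORTHOGONAL**2]) @ R.T


def build_task(rotation_deg: int) -> CategoryTask:
    """Construct one of the four category tasks (rotation 0, 45, 90 or 135).

    The base distributions (rotation 0) are µ_A=(30,50), µ_B=(70,50) with
    SD 2.5 on x (relevant) and 20 on y (irrelevant); other rotations apply a
    rigid rotation about the centre (50,50), which preserves the
    between-mean distance and the covariance eigenvalues.
    """
    if rotation_deg not in ROTATIONS:
        raise ValueError(f"rotation must be one of {ROTATIONS}, got {rotation_deg}")
    R = _rotation_matrix(rotation_deg)
    axis = R @ np.array([1.0, 0.0])
    mean_A = CENTER - MEAN_OFFSET * axis
    mean_B = CENTER + MEAN_OFFSET * axis
    cov = R @ np.diag([SIGMA_RELEVANT_TRAIN**2, SIGMA_ORTHOGONAL**2]) @ R.T
    return CategoryTask(
        rotation_deg=rotation_deg,
        mean_A=mean_A,
        mean_B=mean_B,
        cov_A=cov,
        cov_B=cov.copy(),
        task_class="1D" if rotation_deg in (0, 90) else "2D",
        relevant_axis=axis,
    )


def _sample_truncated_mvn(mean, cov, n, rng, max_iter=1000):
    # rejection-resample draws outside [0,100]^2; mass lost is tiny at these SDs
    out = np.empty((n, 2))
    filled = 0
    for _ in range(max_iter):
        need = n - filled
        if need == 0:
            break
        draws = rng.multivariate_normal(mean, cov, size=need)
        ok = np.all((draws >= 0.0) & (draws <= 100.0), axis=1)
        kept = draws[ok]
        out[filled : filled + len(kept)] = kept
        filled += len(kept)
    if filled < n:
        raise RuntimeError("truncated sampling failed to fill; check task parameters")
    return out


def sample_exemplars(
    task: CategoryTask,
    n: int,
    phase: str = "train",
    rng: np.random.Generator | None = None,
    balance: str = "coin",
) -> pd.DataFrame:
    """Draw ``n`` exemplars from the task's phase-appropriate distributions.

    Coordinates are sampled from the bivariate normal of the drawn category,
    truncated (by rejection) to the [0,100]^2 space.  ``balance="coin"``
    draws the category as an independent fair coin per trial; ``"block"``
    balances categories exactly within consecutive pairs of trials.

    Returns a DataFrame with columns
    ``freq_cpd, ori_rad, x_norm, y_norm, category``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if phase not in ("train", "test"):
        raise ValueError("phase must be 'train' or 'test'")
    rng = np.random.default_rng() if rng is None else rng
    if balance == "coin":
        is_b = rng.random(n) < 0.5
    elif balance == "block":
        is_b = np.empty(n, dtype=bool)
        pattern = np.array([False, True])
        for i in range(0, n, 2):
            blk = rng.permutation(pattern)
            is_b[i : min(i + 2, n)] = blk[: min(2, n - i)]
    else:
        raise ValueError("balance must be 'coin' or 'block'")

    cov = task.cov(phase)
    xy = np.empty((n, 2))
    for cat_is_b in (False, True):
        idx = np.where(is_b == cat_is_b)[0]
        if len(idx):
            mean = task.mean_B if cat_is_b else task.mean_A
            xy[idx] = _sample_truncated_mvn(mean, cov, len(idx), rng)

    return pd.DataFrame(
        {
            "freq_cpd": denormalize_frequency(xy[:, 0]),
            "ori_rad": denormalize_orientation(xy[:, 1]),
            "x_norm": xy[:, 0],
            "y_norm": xy[:, 1],
            "category": np.where(is_b, "B", "A"),
        }
    )


def classify_trial_type(task: CategoryTask, x_norm, y_norm, category) -> np.ndarray:
    """Label testing exemplars as Trained / Proximal / Distal.

    The exemplar is projected onto the task's relevant axis and expressed as
    a signed coordinate ``u`` relative to its category's training mean, with
    positive values pointing toward the category boundary.  ``|u| <= 5``
    (two training SDs) is Trained; ``u > 5`` is Proximal (nearer the
    boundary); ``u < -5`` is Distal (farther from it).
    """
    x_norm = np.atleast_1d(np.asarray(x_norm, dtype=float))
    y_norm = np.atleast_1d(np.asarray(y_norm, dtype=float))
    category = np.atleast_1d(np.asarray(category))
    if not np.all(np.isin(category, ["A", "B"])):
        raise ValueError("category labels must be 'A' or 'B'")
    pts = np.stack([x_norm, y_norm], axis=1)
    means = np.where(
        (category == "A")[:, None], task.mean_A[None, :], task.mean_B[None, :]
    )
    # toward-boundary direction: +axis for A (B lies at +), -axis for B
    sign = np.where(category == "A", 1.0, -1.0)
    u = sign * ((pts - means) @ task.relevant_axis)
    band = TRAINED_BAND_SD * SIGMA_RELEVANT_TRAIN
    out = np.where(np.abs(u) <= band, "Trained", np.where(u > band, "Proximal", "Distal"))
    return out if out.shape[0] > 1 else out
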