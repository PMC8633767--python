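"""The SUSTAIN adaptive clustering network for continuous-dimension category learning.

SUSTAIN represents categories as clusters of similar training experiences.
An incoming stimulus activates each cluster through attention-weighted
receptive fields; clusters compete, and the winner drives a probabilistic
category decision through learned association weights.  Feedback then moves
the winning cluster toward the stimulus, sharpens the per-dimension
attention weights, and adjusts the winner's association weights with a
humble-teacher delta rule.  A *surprising* event — a confident but wrong
decision — recruits a new cluster centred on the current stimulus.

The network starts with no clusters; the first training stimulus seeds the
first cluster, and attention weights start equal across dimensions.

Model equations (two stimulus dimensions, model coordinates in [0,1]^2):

    activation    H_j = sum_i lam_i^r exp(-lam_i * mu_ij) / sum_i lam_i^r,
                  mu_ij = |x_i - pos_{j,i}|
    competition   winner j* = argmax_j H_j  (lowest index on ties);
                  out_{j*} = H_{j*}^beta / sum_k H_k^beta * H_{j*},  others 0
    decision      C_z = sum_j w_{j,z} out_j;  p(z) ∝ exp(d_dec * C_z)
    recruitment   misclassification and H_{j*} > tau  ->  new cluster at x
    updates       pos_{j*} += eta (x - pos_{j*})
                  lam_i    += eta_lambda exp(-lam_i mu_i,j*)(1 - lam_i mu_i,j*)
                  w_{j*,z} += eta (t_z - C_z) out_{j*}   (humble teacher)

This module exposes the single-trial operations for inspection and testing
and a fast :func:`run_training` driver (numba kernel) that reproduces the
stepped Python operations over the same pre-drawn random numbers exactly in
its decisions (choices, winners, recruitment) and to the last ulp in its
float traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import stimuli
from ._kernel import simulate_trials

__all__ = [
    "SustainParams",
    "SustainState",
    "TrialOutcome",
    "TrainingResult",
    "DEFAULT_PARAMS",
    "to_model_coords",
    "cluster_activations",
    "compete",
    "decide",
    "maybe_recruit",
    "update",
    "run_trial",
    "run_training",
    "cluster_categories",
]

MAX_CLUSTERS = 64


@dataclass(frozen=True)
class SustainParams:
    """Free parameters of the network.

    r
        attention focus: exponent weighting high-attention dimensions in the
        cluster activation (dimensionless, >= 0).
    beta
        cluster competition exponent (>= 0); larger values let the winner
        keep more of its activation when other clusters are also active.
    d_dec
        decision consistency (>= 0); softmax gain from category-unit
        activations to choice probabilities (0 = guessing).
    eta
        learning rate for cluster positions and association weights (0-1).
    eta_lambda
        attention learning rate (>= 0); kept separate from ``eta`` so the
        feature-tuning mechanism can be manipulated independently.
    tau
        cluster recruitment threshold (0-1): a misclassified stimulus
        recruits a new cluster only when the winning activation exceeds it
        (the error was "confident", hence surprising).
    """

    r: float = 6.0
    beta: float = 4.0
    d_dec: float = 4.5
    eta: float = 0.03
    eta_lambda: float = 0.0125
    tau: float = 0.50

    def __post_init__(self):
        for name in ("r", "beta", "d_dec", "eta", "eta_lambda", "tau"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.tau <= 1.0:
            raise ValueError("tau must lie in [0, 1]")
        if not 0.0 <= self.eta <= 1.0:
            raise ValueError("eta must lie in [0, 1]")

    def replace(self, **kw) -> "SustainParams":
        d = asdict(self)
        d.update(kw)
        return SustainParams(**d)


#: control configuration used throughout: calibrated so that a full course of
#: training (15 sessions x 80 trials) typically ends with two clusters (one
#: prototype per category) on 1D tasks and several clusters per category on
#: 2D tasks, with end-of-training accuracy well above 75% on both.
DEFAULT_PARAMS = SustainParams()


@dataclass
class SustainState:
    """Mutable network state: cluster positions/associations and attention."""

    positions: np.ndarray = field(
        default_factory=lambda: np.empty((0, 2), dtype=float)
    )
    assoc: np.ndarray = field(default_factory=lambda: np.empty((0, 2), dtype=float))
    lam: np.ndarray = field(default_factory=lambda: np.ones(2, dtype=float))
    n_trials_seen: int = 0

    @property
    def n_clusters(self) -> int:
        return self.positions.shape[0]

    def add_cluster(self, x: np.ndarray) -> int:
        self.positions = np.vstack([self.positions, np.asarray(x, float)[None, :]])
        self.assoc = np.vstack([self.assoc, np.zeros((1, 2))])
        return self.n_clusters - 1


@dataclass
class TrialOutcome:
    """Forward-pass record of a single trial."""

    h_act: np.ndarray
    winner: int
    c_out: np.ndarray
    p: np.ndarray           # choice probabilities over (A, B)
    choice: int             # 0 = A, 1 = B
    correct: bool
    recruited: bool


def to_model_coords(x_norm, y_norm=None):
    """Scale normalized 0-100 stimulus coordinates to the model's [0,1] space."""
    if y_norm is None:
        return np.asarray(x_norm, dtype=float) / 100.0
    return np.array([x_norm, y_norm], dtype=float) / 100.0


def _attention_weights(lam: np.ndarray, r: float) -> np.ndarray:
    # lam^r with the 0^0 = 1 convention; uniform fallback if all weights vanish
    w = np.power(lam, r)
    s = w.sum()
    if s <= 0.0:
        return np.full_like(lam, 1.0 / len(lam))
    return w / s


def cluster_activations(state: SustainState, x: np.ndarray, params: SustainParams) -> np.ndarray:
    """Attention-weighted receptive-field activation of every cluster.

    Each activation lies in (0, 1] and equals 1 exactly when the stimulus
    coincides with the cluster position.
    """
    if state.n_clusters == 0:
        raise ValueError("no clusters in state; seed with the first stimulus")
    mu = np.abs(np.asarray(x, float)[None, :] - state.positions)  # (nc, 2)
    w = _attention_weights(state.lam, params.r)
    e = np.exp(-state.lam[None, :] * mu)
    # explicit multiply-add (not BLAS) so the reference path is bit-identical
    # to the compiled kernel
    return e[:, 0] * w[0] + e[:, 1] * w[1]


def compete(h_act: np.ndarray, beta: float) -> tuple[int, np.ndarray]:
    """Winner-take-all lateral inhibition over cluster activations.

    Returns ``(winner, out)`` where only the winning entry of ``out`` is
    nonzero: out_w = H_w^beta / sum_k H_k^beta * H_w.  Exact ties go to the
    lowest cluster index.
    """
    h_act = np.asarray(h_act, dtype=float)
    if h_act.size == 0:
        raise ValueError("empty activation vector")
    winner = int(np.argmax(h_act))
    out = np.zeros_like(h_act)
    denom = np.sum(h_act**beta)
    out[winner] = h_act[winner] ** beta / denom * h_act[winner]
    return winner, out


def decide(
    state: SustainState,
    out: np.ndarray,
    d_dec: float,
    rng: np.random.Generator | None = None,
    u: float | None = None,
) -> tuple[np.ndarray, np.ndarray, int]:
    """Probabilistic category decision from the winning cluster's output.

    Returns ``(c_out, p, choice)``; the choice is sampled from the softmax
    probabilities using ``u`` (a uniform variate) or ``rng``.
    """
    c_out = state.assoc.T @ out  # (2,)
    z = d_dec * (c_out - c_out.max())
    e = np.exp(z)
    p = e / e.sum()
    if u is None:
        u = (np.random.default_rng() if rng is None else rng).random()
    choice = 0 if u < p[0] else 1
    return c_out, p, choice


def maybe_recruit(
    state: SustainState,
    x: np.ndarray,
    choice: int,
    feedback_category: int,
    h_act: np.ndarray,
    winner: int,
    tau: float,
) -> tuple[int, bool]:
    """Recruit a new cluster after a confident error.

    If the sampled choice disagrees with feedback *and* the winning
    activation exceeds ``tau``, a new cluster is appended at the stimulus
    with zero association weights and becomes the winner for this trial's
    update step.  Returns the (possibly re-designated) winner index and a
    recruitment flag.
    """
    if choice != feedback_category and h_act[winner] > tau and state.n_clusters < MAX_CLUSTERS:
        new = state.add_cluster(x)
        return new, True
    return winner, False


def update(
    state: SustainState,
    x: np.ndarray,
    winner: int,
    out_winner: float,
    c_out: np.ndarray,
    feedback_category: int,
    params: SustainParams,
) -> None:
    """Feedback-driven update of attention, winner position and weights.

    Attention moves along the gradient of the winner's receptive fields
    (fixed point at lam*mu = 1), the winner's position moves toward the
    stimulus, and the winner's association weights follow a humble-teacher
    delta rule: the teacher is clipped so that overshooting the target
    produces no error.
    """
    x = np.asarray(x, dtype=float)
    mu_w = np.abs(x - state.positions[winner])
    lm = state.lam * mu_w
    state.lam = state.lam + params.eta_lambda * np.exp(-lm) * (1.0 - lm)
    np.maximum(state.lam, 0.0, out=state.lam)
    state.positions[winner] += params.eta * (x - state.positions[winner])
    for z in (0, 1):
        t = max(c_out[z], 1.0) if z == feedback_category else min(c_out[z], 0.0)
        state.assoc[winner, z] += params.eta * (t - c_out[z]) * out_winner


def run_trial(
    state: SustainState,
    x: np.ndarray,
    category: int,
    params: SustainParams,
    u_choice: float,
    u_shuffle: float | None = None,
    shuffle_attention: bool = False,
    recruit_on: str = "argmax",
    freeze: bool = False,
) -> TrialOutcome:
    """One complete supervised trial: decide, (maybe) recruit, update.

    ``u_choice`` and ``u_shuffle`` are uniform variates supplied by the
    caller so that stepping this function reproduces the vectorized kernel
    exactly.  ``recruit_on`` selects the error signal gating recruitment:
    ``"argmax"`` (default) uses the model's classification — the category
    unit with the larger activation — so recruitment stops once every
    stimulus region is classified correctly even though the sampled
    behavioural choice still lapses; ``"choice"`` uses the sampled choice
    itself.  ``freeze`` disables recruitment and all updates (used to model
    frozen category representations).
    """
    x = np.asarray(x, dtype=float)
    if shuffle_attention and u_shuffle is not None and u_shuffle < 0.5:
        state.lam = state.lam[::-1].copy()
    seeded = False
    if state.n_clusters == 0:
        state.add_cluster(x)
        seeded = True
    h = cluster_activations(state, x, params)
    winner, out = compete(h, params.beta)
    c_out, p, choice = decide(state, out, params.d_dec, u=u_choice)
    correct = choice == category
    label = choice if recruit_on == "choice" else int(np.argmax(c_out))
    recruited = False
    if not freeze:
        if not seeded:
            winner, recruited = maybe_recruit(
                state, x, label, category, h, winner, params.tau
            )
        if recruited:
            h2 = cluster_activations(state, x, params)
            winner = state.n_clusters - 1  # new cluster is the designated winner
            out = np.zeros_like(h2)
            out[winner] = 1.0 ** params.beta / np.sum(h2**params.beta) * 1.0
            c_up = state.assoc.T @ out
        else:
            c_up = c_out
        update(state, x, winner, out[winner], c_up, category, params)
    state.n_trials_seen += 1
    return TrialOutcome(
        h_act=h, winner=winner, c_out=c_out, p=p,
        choice=choice, correct=bool(correct), recruited=recruited,
    )


@dataclass
class TrainingResult:
    """Per-trial traces and summaries of one simulated course of training."""

    session_acc: np.ndarray        # (n_sessions,) first-attempt accuracy
    correct: np.ndarray            # (n_trials,) 0/1
    p_correct: np.ndarray          # (n_trials,) prob. of the fed-back category
    choice: np.ndarray             # (n_trials,) 0=A, 1=B
    winner: np.ndarray             # (n_trials,)
    recruited: np.ndarray          # (n_trials,) 0/1
    n_clusters_trace: np.ndarray   # (n_trials,)
    lam_trace: np.ndarray          # (n_trials, 2) attention after each trial
    stimuli_xy: np.ndarray         # (n_trials, 2) model coordinates
    categories: np.ndarray         # (n_trials,) 0=A, 1=B
    positions: np.ndarray          # final cluster positions
    assoc: np.ndarray              # final association weights
    n_sessions: int
    trials_per_session: int

    @property
    def n_clusters(self) -> int:
        return self.positions.shape[0]


def _draw_trial_inputs(task, n_trials, rng, balance="coin", phase="train"):
    # numpy-only stimulus stream (same distributions as stimuli.sample_exemplars,
    # without the DataFrame round-trip) — this loop is the simulator's hot path
    if balance == "coin":
        cats = (rng.random(n_trials) < 0.5).astype(np.int64)
    else:
        ex = stimuli.sample_exemplars(task, n_trials, phase=phase, rng=rng, balance=balance)
        xy = ex[["x_norm", "y_norm"]].to_numpy() / 100.0
        cats = (ex["category"].to_numpy() == "B").astype(np.int64)
        return xy, cats, rng.random(n_trials), rng.random(n_trials)
    L = np.linalg.cholesky(task.cov(phase))
    xy = np.empty((n_trials, 2))
    for cat, mean in ((0, task.mean_A), (1, task.mean_B)):
        idx = np.where(cats == cat)[0]
        m = len(idx)
        if m == 0:
            continue
        pts = mean[None, :] + rng.standard_normal((m, 2)) @ L.T
        bad = np.any((pts < 0.0) | (pts > 100.0), axis=1)
        while bad.any():
            k = int(bad.sum())
            pts[bad] = mean[None, :] + rng.standard_normal((k, 2)) @ L.T
            bad = np.any((pts < 0.0) | (pts > 100.0), axis=1)
        xy[idx] = pts
    xy /= 100.0
    u_choice = rng.random(n_trials)
    u_shuffle = rng.random(n_trials)
    return xy, cats, u_choice, u_shuffle


def run_training(
    task: stimuli.CategoryTask,
    params: SustainParams,
    n_sessions: int = 15,
    trials_per_session: int = 80,
    rng: np.random.Generator | int | None = None,
    shuffle_attention: bool = False,
    recruit_on: str = "argmax",
    freeze_after_session: int | None = None,
    balance: str = "coin",
    engine: str = "kernel",
) -> TrainingResult:
    """Simulate a full course of training on one category task.

    Stimuli are drawn from the task's training distributions; the model sees
    first attempts only (correction loops are a property of the behavioural
    task, not of the fitted learning signal).  ``freeze_after_session``
    disables recruitment and all updates from that session onward (0-based),
    modelling an agent whose category representations stop updating.

    The default ``engine="kernel"`` runs a compiled loop; ``engine="python"``
    steps :func:`run_trial` and produces bit-identical traces.
    """
    if n_sessions < 1 or trials_per_session < 1:
        raise ValueError("schedule must be positive")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    n = n_sessions * trials_per_session
    xy, cats, u_choice, u_shuffle = _draw_trial_inputs(task, n, rng, balance)
    freeze_after = -1 if freeze_after_session is None else freeze_after_session * trials_per_session

    if engine == "kernel":
        (correct, p_corr, choice, winner, recruited, nclus, lam_trace,
         positions, assoc, nc) = simulate_trials(
            xy, cats, u_choice, u_shuffle,
            params.r, params.beta, params.d_dec, params.eta,
            params.eta_lambda, params.tau,
            shuffle_attention, recruit_on == "choice", freeze_after, MAX_CLUSTERS,
        )
        positions = positions[:nc].copy()
        assoc = assoc[:nc].copy()
    elif engine == "python":
        state = SustainState()
        correct = np.zeros(n, dtype=np.uint8)
        p_corr = np.zeros(n)
        choice = np.zeros(n, dtype=np.uint8)
        winner = np.zeros(n, dtype=np.int64)
        recruited = np.zeros(n, dtype=np.uint8)
        nclus = np.zeros(n, dtype=np.int64)
        lam_trace = np.zeros((n, 2))
        for t in range(n):
            frozen = freeze_after >= 0 and t >= freeze_after
            o = run_trial(
                state, xy[t], int(cats[t]), params, u_choice[t], u_shuffle[t],
                shuffle_attention=shuffle_attention, recruit_on=recruit_on,
                freeze=frozen,
            )
            correct[t] = o.correct
            p_corr[t] = o.p[cats[t]]
            choice[t] = o.choice
            winner[t] = o.winner
            recruited[t] = o.recruited
            nclus[t] = state.n_clusters
            lam_trace[t] = state.lam
        positions, assoc = state.positions, state.assoc
    else:
        raise ValueError("engine must be 'kernel' or 'python'")

    session_acc = correct.reshape(n_sessions, trials_per_session).mean(axis=1)
    return TrainingResult(
        session_acc=session_acc,
        correct=correct.astype(np.uint8),
        p_correct=p_corr,
        choice=choice.astype(np.uint8),
        winner=winner,
        recruited=recruited.astype(np.uint8),
        n_clusters_trace=nclus,
        lam_trace=lam_trace,
        stimuli_xy=xy,
        categories=cats,
        positions=positions,
        assoc=assoc,
        n_sessions=n_sessions,
        trials_per_session=trials_per_session,
    )


def cluster_categories(assoc: np.ndarray) -> np.ndarray:
    """Assign each cluster to the category of its larger association weight."""
    return np.argmax(assoc, axis=1)
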