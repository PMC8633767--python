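"""Synthetic touchscreen cohorts: SUSTAIN agents playing the category task.

Generates complete trial-level logs with the study's design — two groups
(control and lesion) by two task classes (1D and 2D), 8 subjects per cell,
15 training sessions of 80 trials with correction-trial loops, then 5
testing sessions of 80 trials from the widened testing distributions with
no corrections.  Every subject is an independent SUSTAIN agent; lesion
subjects run a lesion model variant (by default shuffled attention plus a
raised recruitment threshold).  Reaction times and Cue-phase touch
coordinates come from simple generative noise models whose only purpose is
to carry the study's qualitative signatures (cue RT elevated for lesion-1D,
choice RT group-independent, touch separation growing with confidence) into
the behavioural-metrics pipeline.

All randomness derives from a single master seed; regenerating a cohort
with the same configuration is row-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd
import yaml

from . import stimuli
from .behavior import TRIAL_COLUMNS
from .lesions import ModelSpec, effective_params
from .sustain import DEFAULT_PARAMS, SustainParams, run_training

__all__ = ["RTModel", "TouchModel", "CohortConfig", "Cohort",
           "generate_cohort", "make_learning_curves", "save_config", "load_config"]

#: default lesion-agent variant: shuffled attention + raised threshold
DEFAULT_LESION_SPEC = ModelSpec(
    5, shuffle_attention=True, raised_threshold=True, tau_lesion=0.55
)


@dataclass(frozen=True)
class RTModel:
    """Log-normal reaction-time generator.

    Cue RT medians shrink with training progress and are multiplied by
    ``lesion_1d_factor`` for lesion subjects on 1D tasks (the study's cue-RT
    signature); choice RT is group-independent.
    """

    cue_median_start: float = 2.5    # seconds, session 1
    cue_median_end: float = 1.2      # seconds, final session
    choice_median: float = 1.0
    sigma: float = 0.35              # log-scale SD
    lesion_1d_factor: float = 1.3

    def draw(self, progress: float, lesion_1d: bool, rng, n: int = 1):
        med = self.cue_median_start + (self.cue_median_end - self.cue_median_start) * progress
        if lesion_1d:
            med *= self.lesion_1d_factor
        cue = med * np.exp(self.sigma * rng.standard_normal(n))
        choice = self.choice_median * np.exp(self.sigma * rng.standard_normal(n))
        return cue, choice


@dataclass(frozen=True)
class TouchModel:
    """Cue-phase touch x-coordinates (pixels).

    Three touches jitter around the screen centre; the third touch drifts
    toward the chosen side in proportion to choice confidence
    (|p_choice - 0.5|), so the mean third-touch separation equals
    (2/3)*gain*confidence toward the chosen side.
    """

    center_x: float = 320.0
    jitter_sd: float = 15.0
    gain: float = 120.0

    def draw(self, choice_side: str, confidence: float, rng) -> np.ndarray:
        x = self.center_x + self.jitter_sd * rng.standard_normal(3)
        s = 1.0 if choice_side == "right" else -1.0
        x[2] += self.gain * confidence * s
        return x


@dataclass(frozen=True)
class CohortConfig:
    """Study design and agent configuration.

    Defaults reproduce the study's counts exactly: 8 subjects per
    group x task-class cell (split evenly over the two rotations of the
    class), 15 training sessions x 80 trials with correction loops capped at
    10 repeats, and 5 testing sessions x 80 trials without corrections.
    """

    n_per_group: int = 8
    rotations: tuple = (0, 45, 90, 135)
    n_train_sessions: int = 15
    trials_per_session: int = 80
    n_test_sessions: int = 5
    correction_cap: int = 10
    control_params: SustainParams = field(default_factory=lambda: DEFAULT_PARAMS)
    lesion_spec: ModelSpec = field(default_factory=lambda: DEFAULT_LESION_SPEC)
    rt_model: RTModel = field(default_factory=RTModel)
    touch_model: TouchModel = field(default_factory=TouchModel)
    groups: tuple = ("control", "lesion")
    freeze_lesion_clusters_after: int | None = None  # session index; testing option


@dataclass
class Cohort:
    """Generated cohort: trial log, model traces, learning curves, manifest."""

    trials: pd.DataFrame
    traces: pd.DataFrame
    curves: pd.DataFrame
    manifest: dict


def _subject_ids(config: CohortConfig):
    """One (subject_id, group, rotation) triple per virtual subject."""
    out = []
    for group in config.groups:
        for task_class, rots in (("1D", [r for r in config.rotations if r in (0, 90)]),
                                 ("2D", [r for r in config.rotations if r in (45, 135)])):
            if not rots:
                continue
            for i in range(config.n_per_group):
                rot = rots[i % len(rots)]
                out.append((f"{group[0].upper()}{task_class}-{i:02d}", group, rot))
    return out


def generate_cohort(config: CohortConfig | None = None, seed: int = 0) -> Cohort:
    """Simulate a full cohort and return trial logs, traces and curves.

    Training: the agent decides each first attempt and learns from it; on an
    error, correction rows replay the same stimulus with the agent's frozen
    decision state re-sampling a choice each time, until correct or the cap
    is reached.  Testing: stimuli come from the widened distributions, no
    corrections, and agent learning continues (all test choices were
    rewarded in the study).
    """
    cfg = CohortConfig() if config is None else config
    trial_rows = []
    trace_rows = []
    for subj_idx, (sid, group, rot) in enumerate(_subject_ids(cfg)):
        rng = np.random.default_rng([seed, subj_idx])
        task = stimuli.build_task(rot)
        task_class = task.task_class
        lesion = group == "lesion"
        if lesion:
            params = effective_params(cfg.control_params, cfg.lesion_spec)
            shuffle = cfg.lesion_spec.shuffle_attention
        else:
            params, shuffle = cfg.control_params, False
        freeze = cfg.freeze_lesion_clusters_after if lesion else None

        # training phase: first attempts through the agent
        res = run_training(
            task, params,
            n_sessions=cfg.n_train_sessions,
            trials_per_session=cfg.trials_per_session,
            rng=rng, shuffle_attention=shuffle,
            freeze_after_session=freeze,
        )
        n_train = cfg.n_train_sessions * cfg.trials_per_session
        progress = np.repeat(
            np.linspace(0.0, 1.0, cfg.n_train_sessions), cfg.trials_per_session
        )
        lesion_1d = lesion and task_class == "1D"
        for t in range(n_train):
            session = t // cfg.trials_per_session + 1
            trial = t % cfg.trials_per_session + 1
            cat = "A" if res.categories[t] == 0 else "B"
            x, y = res.stimuli_xy[t] * 100.0
            p_corr = res.p_correct[t]
            attempts = [(bool(res.correct[t]),
                         "left" if res.choice[t] == 0 else "right")]
            if not res.correct[t]:
                # correction loop: same stimulus, frozen decision state
                for _ in range(cfg.correction_cap):
                    ok = rng.random() < p_corr
                    side = ("left" if cat == "A" else "right") if ok else \
                           ("right" if cat == "A" else "left")
                    attempts.append((ok, side))
                    if ok:
                        break
            conf = abs(max(p_corr, 1 - p_corr) - 0.5)
            for a_idx, (ok, side) in enumerate(attempts):
                cue, choice_rt = cfg.rt_model.draw(progress[t], lesion_1d, rng)
                touches = cfg.touch_model.draw(side, conf, rng)
                trial_rows.append(
                    (sid, group, rot, session, trial, a_idx > 0, x, y, cat,
                     side, ok, float(cue[0]), float(choice_rt[0]),
                     *np.round(touches, 2))
                )
            trace_rows.append(
                (sid, group, rot, session, trial, x / 100.0, y / 100.0,
                 int(res.winner[t]), int(res.n_clusters_trace[t]),
                 res.lam_trace[t, 0], res.lam_trace[t, 1],
                 p_corr, int(res.choice[t]), bool(res.correct[t]),
                 bool(res.recruited[t]))
            )

        # testing phase: widened distributions, no corrections
        n_test = cfg.n_test_sessions * cfg.trials_per_session
        if n_test:
            from .sustain import SustainState, run_trial

            state = SustainState(
                positions=res.positions.copy(), assoc=res.assoc.copy(),
                lam=res.lam_trace[-1].copy(), n_trials_seen=n_train,
            )
            ex = stimuli.sample_exemplars(task, n_test, phase="test", rng=rng)
            u_choice = rng.random(n_test)
            u_shuffle = rng.random(n_test)
            frozen_test = freeze is not None
            for t in range(n_test):
                session = cfg.n_train_sessions + t // cfg.trials_per_session + 1
                trial = t % cfg.trials_per_session + 1
                cat = ex["category"].iloc[t]
                xy = np.array([ex["x_norm"].iloc[t], ex["y_norm"].iloc[t]]) / 100.0
                o = run_trial(
                    state, xy, 0 if cat == "A" else 1, params,
                    u_choice[t], u_shuffle[t], shuffle_attention=shuffle,
                    freeze=frozen_test,
                )
                side = "left" if o.choice == 0 else "right"
                conf = abs(max(o.p[0], o.p[1]) - 0.5)
                cue, choice_rt = cfg.rt_model.draw(1.0, lesion_1d, rng)
                touches = cfg.touch_model.draw(side, conf, rng)
                trial_rows.append(
                    (sid, group, rot, session, trial, False,
                     ex["x_norm"].iloc[t], ex["y_norm"].iloc[t], cat,
                     side, bool(o.correct), float(cue[0]), float(choice_rt[0]),
                     *np.round(touches, 2))
                )

    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    traces = pd.DataFrame(
        trace_rows,
        columns=["subject_id", "group", "rotation_deg", "session", "trial",
                 "x", "y", "winner", "n_clusters", "lambda_x", "lambda_y",
                 "p_correct", "choice", "correct", "recruited"],
    )
    curves = make_learning_curves(trials, n_train_sessions=cfg.n_train_sessions)
    manifest = {
        "seed": seed,
        "n_subjects": trials["subject_id"].nunique(),
        "config": _config_dict(cfg),
    }
    return Cohort(trials=trials, traces=traces, curves=curves, manifest=manifest)


def make_learning_curves(trials: pd.DataFrame, n_train_sessions: int = 15) -> pd.DataFrame:
    """Group x task-class mean first-attempt training accuracy per session.

    Pooling is the unweighted mean over subjects.  Returns a tidy table with
    columns group, task_class, session, accuracy, n_subjects,
    trials_per_session.
    """
    first = trials.loc[
        ~trials["is_correction"].astype(bool)
        & (trials["session"] <= n_train_sessions)
    ].copy()
    first["task_class"] = np.where(first["rotation_deg"].isin([0, 90]), "1D", "2D")
    per_subj = (
        first.groupby(["group", "task_class", "session", "subject_id"])
        .agg(acc=("correct", "mean"), n_trials=("correct", "size"))
        .reset_index()
    )
    curves = (
        per_subj.groupby(["group", "task_class", "session"])
        .agg(accuracy=("acc", "mean"), n_subjects=("subject_id", "nunique"),
             trials_per_session=("n_trials", "first"))
        .reset_index()
    )
    return curves


def _config_dict(cfg: CohortConfig) -> dict:
    d = asdict(cfg)
    d["control_params"] = asdict(cfg.control_params)
    d["lesion_spec"] = asdict(cfg.lesion_spec)
    d["rt_model"] = asdict(cfg.rt_model)
    d["touch_model"] = asdict(cfg.touch_model)
    d["rotations"] = list(cfg.rotations)
    d["groups"] = list(cfg.groups)
    return d


def save_config(cfg: CohortConfig, path) -> None:
    """Write a cohort configuration as flat YAML."""
    with open(path, "w") as fh:
        yaml.safe_dump(_config_dict(cfg), fh, sort_keys=True)


def load_config(path) -> CohortConfig:
    """Read a cohort configuration written by :func:`save_config`."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    d["control_params"] = SustainParams(**d["control_params"])
    d["lesion_spec"] = ModelSpec(**d["lesion_spec"])
    d["rt_model"] = RTModel(**d["rt_model"])
    d["touch_model"] = TouchModel(**d["touch_model"])
    d["rotations"] = tuple(d["rotations"])
    d["groups"] = tuple(d["groups"])
    return CohortConfig(**d)
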