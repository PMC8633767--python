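"""Fitting SUSTAIN model variants to group-averaged learning curves.

Each candidate model (control plus lesion variants) is optimized to the
per-session accuracy curves of both groups and both task classes at once:
control-group predictions always come from the un-manipulated network,
lesion-group predictions apply the variant's manipulations.  The objective
is the binomial negative log-likelihood of per-session success counts under
the model's Monte-Carlo mean accuracy, and models are compared with
AIC = 2k + 2·NLL.

The simulated objective is made quasi-deterministic through common random
numbers: every evaluation at any parameter vector reuses the same
per-replicate seeds, so the optimizer sees a fixed (if jagged) surface and
identical configuration + seed give bit-identical fits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from . import stimuli
from .lesions import ModelSpec, effective_params
from .sustain import SustainParams, run_training

__all__ = [
    "FitConfig",
    "FitResult",
    "PARAM_NAMES",
    "PARAM_BOUNDS",
    "simulate_mean_curve",
    "curves_frame",
    "fit_model",
    "compare_models",
    "winner_diagnostics",
]

PARAM_NAMES = ("r", "beta", "d_dec", "eta", "eta_lambda", "tau")
#: box bounds for the six shared parameters; eta and eta_lambda carry small
#: positive floors because they are searched on a log scale
PARAM_BOUNDS = {
    "r": (0.0, 10.0),
    "beta": (0.0, 10.0),
    "d_dec": (0.0, 20.0),
    "eta": (1e-3, 1.0),
    "eta_lambda": (1e-4, 2.0),
    "tau": (0.0, 1.0),
    # raised-threshold models add delta in [0,1]; tau_lesion = tau + delta*(1-tau)
    "delta": (0.0, 1.0),
}
#: parameters optimized in log10 units (scale parameters)
LOG_PARAMS = ("eta", "eta_lambda")

ROTATIONS_BY_CLASS = {"1D": (0, 90), "2D": (45, 135)}


@dataclass(frozen=True)
class FitConfig:
    """Optimization settings.

    n_sim
        Monte-Carlo replicates per predicted curve in the polish stage (both
        rotations of a task class are pooled, so a curve averages
        ``2*n_sim`` runs).
    strategy
        ``"global"`` (default): differential evolution over the bounded
        space (Sobol init, ``de_popsize`` population members — the
        multi-start) evaluated at the cheaper ``n_sim_screen`` fidelity,
        then a Nelder-Mead polish at full ``n_sim``.  ``"multistart"``:
        ``n_starts`` Latin-hypercube Nelder-Mead starts, all at full
        ``n_sim``.
    maxfev
        function-evaluation cap per Nelder-Mead search.
    objective
        ``"binomial"`` (default) or ``"sse"`` (Gaussian least squares with
        AIC = n·ln(SSE/n) + 2k).
    extra_starts
        additional polish starts in natural parameter units (tuples ordered
        as PARAM_NAMES + delta); used e.g. to seed a nested model with the
        control model's optimum.
    """

    n_sim: int = 100
    strategy: str = "global"
    n_sim_screen: int = 12
    de_maxiter: int = 25
    de_popsize: int = 8
    n_starts: int = 8
    maxfev: int = 120
    seed: int = 0
    objective: str = "binomial"
    n_sessions: int = 15
    trials_per_session: int = 80
    extra_starts: tuple = ()

    def __post_init__(self):
        if self.objective not in ("binomial", "sse"):
            raise ValueError("objective must be 'binomial' or 'sse'")
        if self.strategy not in ("global", "multistart"):
            raise ValueError("strategy must be 'global' or 'multistart'")


@dataclass
class FitResult:
    """Outcome of fitting one ModelSpec."""

    spec: ModelSpec
    params: SustainParams
    tau_lesion: float | None
    objective: float          # NLL (binomial) or SSE (sse)
    k: int                    # number of free parameters
    aic: float
    sim_curves: pd.DataFrame  # predicted accuracy per group x task_class x session
    converged: bool
    n_evals: int
    config: FitConfig


def _batch_inputs(task, n_runs, n_trials, rng):
    """Pre-draw the stimulus/uniform streams for ``n_runs`` training runs."""
    total = n_runs * n_trials
    cats = (rng.random(total) < 0.5).astype(np.int64)
    L = np.linalg.cholesky(task.cov("train"))
    xy = np.empty((total, 2))
    for cat, mean in ((0, task.mean_A), (1, task.mean_B)):
        idx = np.where(cats == cat)[0]
        pts = mean[None, :] + rng.standard_normal((len(idx), 2)) @ L.T
        bad = np.any((pts < 0.0) | (pts > 100.0), axis=1)
        while bad.any():
            k = int(bad.sum())
            pts[bad] = mean[None, :] + rng.standard_normal((k, 2)) @ L.T
            bad = np.any((pts < 0.0) | (pts > 100.0), axis=1)
        xy[idx] = pts
    xy /= 100.0
    u_choice = rng.random(total)
    u_shuffle = rng.random(total)
    shape = (n_runs, n_trials)
    return (xy.reshape(n_runs, n_trials, 2), cats.reshape(shape),
            u_choice.reshape(shape), u_shuffle.reshape(shape))


def simulate_mean_curve(
    params: SustainParams,
    task_class: str,
    n_sim: int,
    seed: int,
    shuffle_attention: bool = False,
    n_sessions: int = 15,
    trials_per_session: int = 80,
) -> np.ndarray:
    """Monte-Carlo mean learning curve for one task class.

    Both rotations of the class (0/90 or 45/135) are pooled with equal
    weight.  Rotation ``j`` always uses the seed sequence ``(seed, j)`` for
    its whole batch of replicates, giving common random numbers across
    parameter evaluations.
    """
    if n_sim < 1:
        raise ValueError("n_sim must be >= 1")
    from ._kernel import simulate_trials
    from .sustain import MAX_CLUSTERS

    rots = ROTATIONS_BY_CLASS[task_class]
    n_trials = n_sessions * trials_per_session
    acc = np.zeros(n_sessions)
    for j, rot in enumerate(rots):
        task = stimuli.build_task(rot)
        rng = np.random.default_rng([seed, j])
        xy, cats, u_choice, u_shuffle = _batch_inputs(task, n_sim, n_trials, rng)
        for i in range(n_sim):
            correct = simulate_trials(
                xy[i], cats[i], u_choice[i], u_shuffle[i],
                params.r, params.beta, params.d_dec, params.eta,
                params.eta_lambda, params.tau,
                shuffle_attention, False, -1, MAX_CLUSTERS,
            )[0]
            acc += correct.reshape(n_sessions, trials_per_session).mean(axis=1)
    return acc / (len(rots) * n_sim)


def curves_frame(curves: pd.DataFrame) -> pd.DataFrame:
    """Validate a tidy learning-curve table (one row per condition-session).

    Expected columns: group, task_class, session, accuracy, n_subjects,
    trials_per_session.
    """
    required = {"group", "task_class", "session", "accuracy",
                "n_subjects", "trials_per_session"}
    missing = required - set(curves.columns)
    if missing:
        raise ValueError(f"curves table missing columns: {sorted(missing)}")
    return curves.sort_values(["group", "task_class", "session"]).reset_index(drop=True)


def _search_bounds(names):
    """Box bounds in search units (log10 for scale parameters)."""
    lo, hi = [], []
    for n in names:
        a, b = PARAM_BOUNDS[n]
        if n in LOG_PARAMS:
            a, b = np.log10(a), np.log10(b)
        lo.append(a)
        hi.append(b)
    return np.array(lo), np.array(hi)


def _from_search(theta, names):
    """Search units -> natural units."""
    out = []
    for v, n in zip(theta, names):
        out.append(10.0**v if n in LOG_PARAMS else v)
    return np.array(out)


def _to_search(values, names):
    out = []
    for v, n in zip(values, names):
        out.append(np.log10(max(v, PARAM_BOUNDS[n][0])) if n in LOG_PARAMS else v)
    return np.array(out)


def _theta_to_params(theta: np.ndarray, spec: ModelSpec):
    """Natural-unit vector -> (SustainParams, tau_lesion)."""
    p = SustainParams(**dict(zip(PARAM_NAMES, np.asarray(theta[:6], dtype=float))))
    tau_lesion = None
    if spec.raised_threshold:
        delta = float(theta[6])
        tau_lesion = p.tau + delta * (1.0 - p.tau)
    return p, tau_lesion


def _predicted_curves(params, spec, tau_lesion, cfg: FitConfig) -> pd.DataFrame:
    rows = []
    lesion_spec = spec if not spec.raised_threshold else spec.with_tau_lesion(tau_lesion)
    p_lesion = effective_params(params, lesion_spec)
    lesion_is_control = (p_lesion == params) and not lesion_spec.shuffle_attention
    for task_class in ("1D", "2D"):
        pred_c = simulate_mean_curve(
            params, task_class, cfg.n_sim, cfg.seed,
            n_sessions=cfg.n_sessions, trials_per_session=cfg.trials_per_session,
        )
        if lesion_is_control:
            pred_l = pred_c
        else:
            pred_l = simulate_mean_curve(
                p_lesion, task_class, cfg.n_sim, cfg.seed,
                shuffle_attention=lesion_spec.shuffle_attention,
                n_sessions=cfg.n_sessions, trials_per_session=cfg.trials_per_session,
            )
        for s in range(cfg.n_sessions):
            rows.append(("control", task_class, s + 1, pred_c[s]))
            rows.append(("lesion", task_class, s + 1, pred_l[s]))
    return pd.DataFrame(rows, columns=["group", "task_class", "session", "accuracy"])


def _objective_value(pred: pd.DataFrame, curves: pd.DataFrame, kind: str) -> float:
    merged = curves.merge(
        pred, on=["group", "task_class", "session"], suffixes=("", "_pred")
    )
    if len(merged) != len(curves):
        raise ValueError("predicted curves do not cover the observed conditions")
    p = np.clip(merged["accuracy_pred"].to_numpy(), 1e-4, 1 - 1e-4)
    if kind == "sse":
        return float(np.sum((merged["accuracy"].to_numpy() - p) ** 2))
    n = (merged["n_subjects"] * merged["trials_per_session"]).to_numpy()
    k = np.rint(merged["accuracy"].to_numpy() * n)
    return float(-np.sum(k * np.log(p) + (n - k) * np.log(1 - p)))


def fit_model(spec: ModelSpec, curves: pd.DataFrame, config: FitConfig | None = None) -> FitResult:
    """Fit one model variant to observed learning curves.

    Default strategy: a global differential-evolution search at reduced
    Monte-Carlo fidelity followed by a bounded Nelder-Mead polish at full
    fidelity (see :class:`FitConfig`).  Control-model parameters are shared
    across groups; lesion manipulations shape only the lesion group's
    predictions.  For raised-threshold models the control-equivalent point
    (tau_lesion == tau) is included as a polish start, and
    ``config.extra_starts`` can seed the polish with another model's
    optimum, which makes the nesting relation control ⊆ raised-threshold
    hold exactly under common random numbers.
    """
    cfg = FitConfig() if config is None else config
    curves = curves_frame(curves)
    names = list(PARAM_NAMES) + (["delta"] if spec.raised_threshold else [])
    lo, hi = _search_bounds(names)
    n_evals = 0

    # pre-extract observed data once; the per-eval objective is pure numpy
    obs_group = curves["group"].to_numpy()
    obs_class = curves["task_class"].to_numpy()
    obs_session = curves["session"].to_numpy(dtype=int)
    obs_acc = curves["accuracy"].to_numpy(dtype=float)
    obs_n = (curves["n_subjects"] * curves["trials_per_session"]).to_numpy(dtype=float)
    obs_k = np.rint(obs_acc * obs_n)

    def make_objective(fit_cfg):
        def objective(theta):
            nonlocal n_evals
            n_evals += 1
            nat = _from_search(np.clip(theta, lo, hi), names)
            params, tau_lesion = _theta_to_params(nat, spec)
            lesion_spec = spec if not spec.raised_threshold else spec.with_tau_lesion(tau_lesion)
            p_lesion = effective_params(params, lesion_spec)
            lesion_is_control = (p_lesion == params) and not lesion_spec.shuffle_attention
            pred = np.empty(len(obs_acc))
            for task_class in ("1D", "2D"):
                c = simulate_mean_curve(
                    params, task_class, fit_cfg.n_sim, fit_cfg.seed,
                    n_sessions=fit_cfg.n_sessions,
                    trials_per_session=fit_cfg.trials_per_session,
                )
                l = c if lesion_is_control else simulate_mean_curve(
                    p_lesion, task_class, fit_cfg.n_sim, fit_cfg.seed,
                    shuffle_attention=lesion_spec.shuffle_attention,
                    n_sessions=fit_cfg.n_sessions,
                    trials_per_session=fit_cfg.trials_per_session,
                )
                m = obs_class == task_class
                pred[m & (obs_group == "control")] = c[obs_session[m & (obs_group == "control")] - 1]
                pred[m & (obs_group == "lesion")] = l[obs_session[m & (obs_group == "lesion")] - 1]
            p = np.clip(pred, 1e-4, 1 - 1e-4)
            if cfg.objective == "sse":
                return float(np.sum((obs_acc - p) ** 2))
            return float(-np.sum(obs_k * np.log(p) + (obs_n - obs_k) * np.log(1 - p)))
        return objective

    obj_full = make_objective(cfg)
    polish_starts = [_to_search(s, names) for s in cfg.extra_starts]
    converged = False
    if cfg.strategy == "global":
        screen_cfg = FitConfig(
            n_sim=cfg.n_sim_screen, seed=cfg.seed, objective=cfg.objective,
            n_sessions=cfg.n_sessions, trials_per_session=cfg.trials_per_session,
        )
        de = optimize.differential_evolution(
            make_objective(screen_cfg), list(zip(lo, hi)),
            maxiter=cfg.de_maxiter, popsize=cfg.de_popsize, seed=cfg.seed,
            tol=0.005, polish=False, init="sobol",
        )
        polish_starts.append(de.x)
        converged = bool(de.success)
    elif cfg.n_starts > 0:
        sampler = qmc.LatinHypercube(d=len(names), seed=cfg.seed)
        polish_starts.extend(qmc.scale(sampler.random(cfg.n_starts), lo, hi))
    if not polish_starts:
        raise ValueError("no optimizer starts: set n_starts or extra_starts")
    if spec.raised_threshold and not cfg.extra_starts:
        mid = 0.5 * (lo + hi)
        mid[-1] = lo[-1]  # control-equivalent start: tau_lesion == tau
        polish_starts.append(mid)

    best = None
    for x0 in polish_starts:
        res = optimize.minimize(
            obj_full, np.clip(x0, lo, hi), method="Nelder-Mead",
            bounds=optimize.Bounds(lo, hi),
            options={"maxfev": cfg.maxfev, "xatol": 1e-3, "fatol": 0.5,
                     "adaptive": True},
        )
        if best is None or res.fun < best.fun:
            best = res
        converged = converged or bool(res.success)

    theta = _from_search(np.clip(best.x, lo, hi), names)
    params, tau_lesion = _theta_to_params(theta, spec)
    k = len(names)
    obj = float(best.fun)
    if cfg.objective == "binomial":
        aic = 2.0 * k + 2.0 * obj
    else:
        n_pts = len(curves)
        aic = n_pts * np.log(max(obj, 1e-12) / n_pts) + 2.0 * k
    return FitResult(
        spec=spec, params=params, tau_lesion=tau_lesion, objective=obj,
        k=k, aic=float(aic),
        sim_curves=_predicted_curves(params, spec, tau_lesion, cfg),
        converged=converged, n_evals=n_evals, config=cfg,
    )


def compare_models(results: list["FitResult"]) -> pd.DataFrame:
    """Rank fitted models by ascending AIC (row 0 is the winner)."""
    if not results:
        raise ValueError("no fit results to compare")
    df = pd.DataFrame(
        {
            "model_id": [r.spec.model_id for r in results],
            "k": [r.k for r in results],
            "objective": [r.objective for r in results],
            "aic": [r.aic for r in results],
        }
    ).sort_values("aic").reset_index(drop=True)
    df["delta_aic"] = df["aic"] - df["aic"].iloc[0]
    return df


def winner_diagnostics(result: FitResult, n_sim: int = 20, seed: int = 0) -> dict:
    """Cluster-count and attention readouts of a fitted model.

    Simulates ``n_sim`` runs per group x task_class x rotation with the
    fitted parameters and returns, per condition: mean and modal total
    cluster count, mean clusters per category (each cluster assigned to the
    category of its larger association weight), and the per-trial mean
    attention weight on the relevant and irrelevant dimensions (for 2D
    rotations "relevant" is the x-like rotated axis; the two are
    statistically equivalent there).
    """
    out = {}
    spec = result.spec
    lesion_spec = spec if not spec.raised_threshold else spec.with_tau_lesion(result.tau_lesion)
    for group in ("control", "lesion"):
        if group == "control":
            params, shuffle = result.params, False
        else:
            params = effective_params(result.params, lesion_spec)
            shuffle = lesion_spec.shuffle_attention
        for task_class, rots in ROTATIONS_BY_CLASS.items():
            counts, percat, lam_rel, lam_irr = [], [], [], []
            for j, rot in enumerate(rots):
                task = stimuli.build_task(rot)
                for i in range(n_sim):
                    rng = np.random.default_rng([seed, 7 + j, i])
                    res = run_training(task, params, rng=rng, shuffle_attention=shuffle)
                    counts.append(res.n_clusters)
                    cats = np.argmax(res.assoc, axis=1)
                    percat.append(0.5 * (np.sum(cats == 0) + np.sum(cats == 1)))
                    rel = 0 if rot in (0, 45) else 1
                    lam_rel.append(res.lam_trace[:, rel])
                    lam_irr.append(res.lam_trace[:, 1 - rel])
            counts = np.array(counts)
            vals, freq = np.unique(counts, return_counts=True)
            out[(group, task_class)] = {
                "mean_clusters": float(counts.mean()),
                "modal_clusters": int(vals[np.argmax(freq)]),
                "mean_clusters_per_category": float(np.mean(percat)),
                "lam_relevant": np.mean(lam_rel, axis=0),
                "lam_irrelevant": np.mean(lam_irr, axis=0),
            }
    return out
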