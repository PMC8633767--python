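"""SUSTAIN network: single-trial operations, learning dynamics, kernel parity."""

import math

import numpy as np
import pytest
from scipy import stats

from ratcat import build_task
from ratcat.sustain import (
    DEFAULT_PARAMS,
    SustainParams,
    SustainState,
    cluster_activations,
    compete,
    decide,
    maybe_recruit,
    run_training,
    to_model_coords,
    update,
)


def make_state(positions, assoc, lam=(1.0, 1.0)):
    return SustainState(
        positions=np.array(positions, dtype=float),
        assoc=np.array(assoc, dtype=float),
        lam=np.array(lam, dtype=float),
    )


def test_to_model_coords():
    assert np.allclose(to_model_coords(30.0, 50.0), [0.30, 0.50])
    assert np.allclose(to_model_coords(0.0, 0.0), [0.0, 0.0])
    assert np.allclose(to_model_coords(70.0, 50.0), [0.70, 0.50])


class TestClusterActivations:
    def test_activation_is_one_at_cluster_position(self):
        s = make_state([[0.3, 0.5]], [[0, 0]])
        h = cluster_activations(s, [0.3, 0.5], DEFAULT_PARAMS)
        assert h[0] == pytest.approx(1.0, abs=1e-15)

    def test_hand_example(self):
        # lam=(1,1), r=1, mu=(0.2,0.4): (e^-0.2 + e^-0.4)/2
        s = make_state([[0.0, 0.0]], [[0, 0]], lam=(1.0, 1.0))
        p = SustainParams(r=1.0)
        h = cluster_activations(s, [0.2, 0.4], p)
        assert h[0] == pytest.approx(0.744525, abs=1e-5)

    def test_r_zero_neutralizes_attention_weighting(self):
        # with r=0 the lam^r mixing weights are uniform whatever lam is
        p = SustainParams(r=0.0)
        s1 = make_state([[0.0, 0.0]], [[0, 0]], lam=(1.0, 1.0))
        s2 = make_state([[0.0, 0.0]], [[0, 0]], lam=(1.0, 1.0))
        h1 = cluster_activations(s1, [0.2, 0.4], SustainParams(r=1.0))
        h2 = cluster_activations(s2, [0.2, 0.4], p)
        assert h1[0] == pytest.approx(h2[0], abs=1e-12)

    def test_empty_state_raises(self):
        with pytest.raises(ValueError):
            cluster_activations(SustainState(), [0.1, 0.1], DEFAULT_PARAMS)


class TestCompete:
    def test_single_cluster_passes_through(self):
        w, out = compete(np.array([0.8]), beta=3.0)
        assert w == 0
        assert out[0] == pytest.approx(0.8)

    def test_hand_example(self):
        w, out = compete(np.array([0.8, 0.4]), beta=1.0)
        assert w == 0
        assert out[0] == pytest.approx(0.8**2 / 1.2, abs=1e-12)
        assert out[1] == 0.0

    def test_tie_goes_to_lowest_index(self):
        w, out = compete(np.array([0.5, 0.5]), beta=1.0)
        assert w == 0
        assert out[0] == pytest.approx(0.25)
        assert out[1] == 0.0


class TestDecide:
    def test_flat_softmax_when_d_zero(self):
        s = make_state([[0, 0]], [[5.0, -2.0]])
        _, p, _ = decide(s, np.array([1.0]), d_dec=0.0, u=0.3)
        assert np.allclose(p, [0.5, 0.5])

    def test_hand_example(self):
        # C=(1,0), d=2: p(A) = e^2/(e^2+1)
        s = make_state([[0, 0]], [[1.0, 0.0]])
        c, p, _ = decide(s, np.array([1.0]), d_dec=2.0, u=0.5)
        assert np.allclose(c, [1.0, 0.0])
        assert p[0] == pytest.approx(math.e**2 / (math.e**2 + 1), abs=1e-12)

    def test_fresh_cluster_guesses(self):
        s = make_state([[0, 0]], [[0.0, 0.0]])
        _, p, _ = decide(s, np.array([0.7]), d_dec=10.0, u=0.9)
        assert np.allclose(p, [0.5, 0.5])

    def test_probabilities_sum_to_one(self, rng):
        for _ in range(50):
            nc = rng.integers(1, 6)
            s = make_state(rng.random((nc, 2)), rng.normal(size=(nc, 2)))
            out = np.zeros(nc)
            out[rng.integers(nc)] = rng.random()
            _, p, _ = decide(s, out, d_dec=rng.random() * 20, u=rng.random())
            assert abs(p.sum() - 1.0) < 1e-12


class TestRecruitment:
    def test_correct_trial_never_recruits(self):
        s = make_state([[0.3, 0.5]], [[1.0, 0.0]])
        w, rec = maybe_recruit(s, np.array([0.4, 0.5]), 0, 0, np.array([0.9]), 0, 0.5)
        assert not rec and w == 0 and s.n_clusters == 1

    def test_confident_error_recruits(self):
        s = make_state([[0.3, 0.5]], [[1.0, 0.0]])
        w, rec = maybe_recruit(s, np.array([0.4, 0.5]), 0, 1, np.array([0.9]), 0, 0.5)
        assert rec and w == 1 and s.n_clusters == 2
        assert np.allclose(s.positions[1], [0.4, 0.5])
        assert np.allclose(s.assoc[1], [0.0, 0.0])

    def test_unconfident_error_does_not_recruit(self):
        s = make_state([[0.3, 0.5]], [[1.0, 0.0]])
        w, rec = maybe_recruit(s, np.array([0.4, 0.5]), 0, 1, np.array([0.3]), 0, 0.5)
        assert not rec and s.n_clusters == 1


class TestUpdate:
    def test_zero_learning_rates_leave_state_unchanged(self):
        s = make_state([[0.3, 0.5]], [[0.4, 0.1]], lam=(2.0, 1.5))
        p = SustainParams(eta=0.0, eta_lambda=0.0)
        update(s, np.array([0.6, 0.2]), 0, 0.5, np.array([0.2, 0.05]), 0, p)
        assert np.allclose(s.positions, [[0.3, 0.5]])
        assert np.allclose(s.assoc, [[0.4, 0.1]])
        assert np.allclose(s.lam, [2.0, 1.5])

    def test_attention_fixed_point_at_lam_mu_one(self):
        # lam*mu = 1 on both dimensions -> no attention change
        s = make_state([[0.0, 0.0]], [[0, 0]], lam=(2.0, 4.0))
        x = np.array([0.5, 0.25])  # mu = (0.5, 0.25); lam*mu = (1, 1)
        p = SustainParams(eta=0.0, eta_lambda=0.3)
        update(s, x, 0, 0.5, np.array([0.0, 0.0]), 0, p)
        assert np.allclose(s.lam, [2.0, 4.0], atol=1e-12)

    def test_attention_gain_at_zero_distance(self):
        s = make_state([[0.5, 0.5]], [[0, 0]], lam=(1.0, 1.0))
        p = SustainParams(eta=0.0, eta_lambda=0.1)
        update(s, np.array([0.5, 0.5]), 0, 0.5, np.array([0.0, 0.0]), 0, p)
        assert np.allclose(s.lam, [1.1, 1.1], atol=1e-12)


def _oracle_forward(positions, assoc, lam, x, r, beta, d):
    """Straight-line recomputation of the forward pass with scalar math."""
    nc = len(positions)
    wsum = sum(l**r for l in lam)
    h = []
    for j in range(nc):
        acc = 0.0
        for i in range(2):
            acc += (lam[i] ** r / wsum) * math.exp(-lam[i] * abs(x[i] - positions[j][i]))
        h.append(acc)
    win = max(range(nc), key=lambda j: (h[j], -j))
    out_w = h[win] ** beta / sum(v**beta for v in h) * h[win]
    c = [assoc[win][0] * out_w, assoc[win][1] * out_w]
    m = max(c)
    e = [math.exp(d * (v - m)) for v in c]
    p = [e[0] / (e[0] + e[1]), e[1] / (e[0] + e[1])]
    return h, win, c, p


def test_forward_pass_matches_scalar_oracle(rng):
    """Package forward pass equals an independent scalar-arithmetic oracle."""
    for _ in range(10):
        nc = int(rng.integers(1, 7))
        positions = rng.random((nc, 2))
        assoc = rng.normal(size=(nc, 2))
        lam = rng.random(2) * 4 + 0.1
        x = rng.random(2)
        r, beta, d = rng.random() * 8, rng.random() * 6, rng.random() * 15
        s = make_state(positions, assoc, lam)
        params = SustainParams(r=r, beta=beta, d_dec=d)
        h = cluster_activations(s, x, params)
        win, out = compete(h, beta)
        c, p, _ = decide(s, out, d, u=0.5)
        oh, owin, oc, op = _oracle_forward(positions, assoc, lam, x, r, beta, d)
        assert np.allclose(h, oh, atol=1e-10)
        assert win == owin
        assert np.allclose(c, oc, atol=1e-10)
        assert np.allclose(p, op, atol=1e-10)


@pytest.mark.parametrize("rot, shuffle, freeze", [(0, False, None), (45, False, None),
                                                  (90, True, None), (135, False, 3)])
def test_kernel_matches_python_reference(tasks, rot, shuffle, freeze):
    """The compiled training loop is bit-identical to stepping run_trial."""
    kw = dict(shuffle_attention=shuffle, freeze_after_session=freeze,
              n_sessions=5, trials_per_session=40)
    a = run_training(tasks[rot], DEFAULT_PARAMS, rng=11, engine="kernel", **kw)
    b = run_training(tasks[rot], DEFAULT_PARAMS, rng=11, engine="python", **kw)
    # decision traces agree exactly; float traces agree to the last ulp or
    # two (compiled pow/exp may round differently than numpy's)
    assert np.array_equal(a.correct, b.correct)
    assert np.array_equal(a.choice, b.choice)
    assert np.array_equal(a.winner, b.winner)
    assert np.array_equal(a.n_clusters_trace, b.n_clusters_trace)
    assert np.array_equal(a.recruited, b.recruited)
    for x, y in ((a.lam_trace, b.lam_trace), (a.positions, b.positions),
                 (a.assoc, b.assoc), (a.p_correct, b.p_correct)):
        assert np.allclose(x, y, rtol=1e-9, atol=1e-12)


def test_learning_curve_rises_from_near_chance(tasks):
    """Accuracy starts near guessing and ends above 0.75 on a 1D task."""
    early, late, first_trials = [], [], []
    for s in range(20):
        res = run_training(tasks[0 if s % 2 == 0 else 90], DEFAULT_PARAMS, rng=300 + s)
        early.append(res.session_acc[0])
        late.append(res.session_acc[-1])
        first_trials.append(res.correct[:10].mean())
    assert np.mean(first_trials) < 0.65      # first few trials ~ guessing
    assert np.mean(late) > 0.75
    assert np.mean(late) > np.mean(early)


def test_modal_cluster_count_is_two_on_1d(tasks):
    counts = [run_training(tasks[0 if s % 2 == 0 else 90], DEFAULT_PARAMS,
                           rng=500 + s).n_clusters for s in range(20)]
    vals, freq = np.unique(counts, return_counts=True)
    assert vals[np.argmax(freq)] == 2


def test_attention_stays_balanced_on_2d(tasks):
    """On 2D tasks both dimensions are relevant: no systematic lambda split."""
    diffs = [run_training(tasks[45 if s % 2 == 0 else 135], DEFAULT_PARAMS,
                          rng=700 + s).lam_trace[-80:].mean(axis=0) for s in range(20)]
    diffs = np.array([d[0] - d[1] for d in diffs])
    t, p = stats.ttest_1samp(diffs, 0.0)
    assert p > 0.01


def test_attention_separates_on_1d(tasks):
    """lambda on the relevant dimension ends above the irrelevant one (1D)."""
    seps = []
    for s in range(20):
        rot = 0 if s % 2 == 0 else 90
        rel = 0 if rot == 0 else 1
        res = run_training(tasks[rot], DEFAULT_PARAMS, rng=900 + s)
        lam = res.lam_trace[-80:].mean(axis=0)
        seps.append(lam[rel] - lam[1 - rel])
    t, p = stats.ttest_1samp(seps, 0.0, alternative="greater")
    assert p < 0.05


def test_static_attention_is_inert(tasks):
    """With r=0 and eta_lambda=0, permuting attention weights every trial
    leaves the final-accuracy distribution unchanged (KS test)."""
    p_static = DEFAULT_PARAMS.replace(r=0.0, eta_lambda=0.0)
    base = [run_training(tasks[0], p_static, rng=1100 + s).session_acc[-3:].mean()
            for s in range(50)]
    perm = [run_training(tasks[0], p_static, rng=1100 + s,
                         shuffle_attention=True).session_acc[-3:].mean()
            for s in range(50)]
    assert stats.ks_2samp(base, perm).pvalue > 0.01


def test_raised_threshold_reduces_recruitment_on_2d(tasks):
    """On 2D tasks, where several clusters per category are recruited, a
    higher surprise threshold monotonically thins recruitment.  (On 1D
    tasks a very high threshold can instead starve the second category's
    cluster and inflate late recruitment, so the relation is not global.)"""
    means = []
    for tau in (0.3, 0.5, 0.7, 0.9):
        p = DEFAULT_PARAMS.replace(tau=tau)
        counts = [run_training(tasks[45], p, rng=1300 + s).n_clusters
                  for s in range(50)]
        means.append(np.mean(counts))
    assert all(a >= b for a, b in zip(means, means[1:]))


def test_run_training_rejects_bad_schedule(tasks):
    with pytest.raises(ValueError):
        run_training(tasks[0], DEFAULT_PARAMS, n_sessions=0)
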