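"""Compiled inner loop for SUSTAIN training simulations.

The kernel consumes pre-drawn stimuli and uniform variates so that it is a
pure function of its inputs; :func:`ratcat.sustain.run_training` with
``engine="python"`` steps the reference implementation over the same inputs
and must reproduce the kernel's decisions exactly and its float traces to
within rounding of the transcendental functions (this equivalence is under
test).
"""

from __future__ import annotations

import numpy as np
from numba import njit

__all__ = ["simulate_trials"]


@njit(cache=True)
def simulate_trials(
    xy,            # (n, 2) stimuli in model coordinates [0,1]^2
    cats,          # (n,) int64 feedback category, 0=A 1=B
    u_choice,      # (n,) uniforms for choice sampling
    u_shuffle,     # (n,) uniforms for attention shuffling
    r, beta, d_dec, eta, eta_lam, tau,
    shuffle_attention,  # bool: permute attention weights before each trial
    recruit_sampled,    # bool: recruit on the sampled choice instead of argmax
    freeze_after,       # trial index from which updates stop; -1 = never
    max_clusters,
):
    n = xy.shape[0]
    pos = np.zeros((max_clusters, 2))
    assoc = np.zeros((max_clusters, 2))
    lam = np.ones(2)
    nc = 0

    correct = np.zeros(n, dtype=np.uint8)
    p_correct = np.zeros(n)
    choice_arr = np.zeros(n, dtype=np.uint8)
    winner_arr = np.zeros(n, dtype=np.int64)
    recruited = np.zeros(n, dtype=np.uint8)
    nclus = np.zeros(n, dtype=np.int64)
    lam_trace = np.zeros((n, 2))

    h = np.zeros(max_clusters)

    for t in range(n):
        frozen = freeze_after >= 0 and t >= freeze_after
        if shuffle_attention and u_shuffle[t] < 0.5:
            tmp = lam[0]
            lam[0] = lam[1]
            lam[1] = tmp
        seeded = False
        if nc == 0:
            pos[0, 0] = xy[t, 0]
            pos[0, 1] = xy[t, 1]
            assoc[0, 0] = 0.0
            assoc[0, 1] = 0.0
            nc = 1
            seeded = True

        # attention mixing weights lam^r (0^0 = 1 convention)
        w0 = lam[0] ** r
        w1 = lam[1] ** r
        ws = w0 + w1
        if ws <= 0.0:
            w0 = 0.5
            w1 = 0.5
        else:
            w0 /= ws
            w1 /= ws

        # cluster activations
        winner = 0
        hmax = -1.0
        for j in range(nc):
            mu0 = abs(xy[t, 0] - pos[j, 0])
            mu1 = abs(xy[t, 1] - pos[j, 1])
            hj = w0 * np.exp(-lam[0] * mu0) + w1 * np.exp(-lam[1] * mu1)
            h[j] = hj
            if hj > hmax:
                hmax = hj
                winner = j

        # competition: only the winner projects forward
        denom = 0.0
        for j in range(nc):
            denom += h[j] ** beta
        out_w = hmax**beta / denom * hmax

        # decision
        c0 = assoc[winner, 0] * out_w
        c1 = assoc[winner, 1] * out_w
        m = c0 if c0 > c1 else c1
        e0 = np.exp(d_dec * (c0 - m))
        e1 = np.exp(d_dec * (c1 - m))
        p0 = e0 / (e0 + e1)
        p1 = e1 / (e0 + e1)
        choice = 0 if u_choice[t] < p0 else 1
        cat = cats[t]
        ok = choice == cat
        p_correct[t] = p0 if cat == 0 else p1

        # recruitment label: the model's classification (argmax) by default,
        # or the sampled behavioural choice when recruit_sampled is set
        if recruit_sampled:
            label = choice
        else:
            label = 0 if c0 >= c1 else 1
        rec = False
        if not frozen:
            if (not seeded) and label != cat and hmax > tau and nc < max_clusters:
                # recruit: new cluster at the stimulus becomes the winner
                pos[nc, 0] = xy[t, 0]
                pos[nc, 1] = xy[t, 1]
                assoc[nc, 0] = 0.0
                assoc[nc, 1] = 0.0
                winner = nc
                nc += 1
                rec = True
                denom = 0.0
                for j in range(nc):
                    mu0 = abs(xy[t, 0] - pos[j, 0])
                    mu1 = abs(xy[t, 1] - pos[j, 1])
                    h[j] = w0 * np.exp(-lam[0] * mu0) + w1 * np.exp(-lam[1] * mu1)
                    denom += h[j] ** beta
                out_w = 1.0**beta / denom * 1.0
                c0 = 0.0
                c1 = 0.0

            # updates: attention (fixed point at lam*mu = 1), position, weights
            mu0 = abs(xy[t, 0] - pos[winner, 0])
            mu1 = abs(xy[t, 1] - pos[winner, 1])
            lm0 = lam[0] * mu0
            lm1 = lam[1] * mu1
            lam[0] += eta_lam * np.exp(-lm0) * (1.0 - lm0)
            lam[1] += eta_lam * np.exp(-lm1) * (1.0 - lm1)
            if lam[0] < 0.0:
                lam[0] = 0.0
            if lam[1] < 0.0:
                lam[1] = 0.0
            pos[winner, 0] += eta * (xy[t, 0] - pos[winner, 0])
            pos[winner, 1] += eta * (xy[t, 1] - pos[winner, 1])
            # humble teacher: no error on overshoot
            t0 = max(c0, 1.0) if cat == 0 else min(c0, 0.0)
            t1 = max(c1, 1.0) if cat == 1 else min(c1, 0.0)
            assoc[winner, 0] += eta * (t0 - c0) * out_w
            assoc[winner, 1] += eta * (t1 - c1) * out_w

        correct[t] = 1 if ok else 0
        choice_arr[t] = choice
        winner_arr[t] = winner
        recruited[t] = 1 if rec else 0
        nclus[t] = nc
        lam_trace[t, 0] = lam[0]
        lam_trace[t, 1] = lam[1]

    return (
        correct, p_correct, choice_arr, winner_arr, recruited, nclus,
        lam_trace, pos, assoc, nc,
    )
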