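"""Numba kernels for the simulated-annealing minimum-set solver.

The problem is stored in CSR form: ``indptr``/``feat_idx``/``feat_amt`` map
each planning unit to the features it contains and their amounts, so a
single-unit flip is evaluated in O(features in that unit).
"""

from __future__ import annotations

import numpy as np
from numba import njit


@njit(inline="always")
def _flip_delta(u, sel, rep, costs, indptr, feat_idx, feat_amt, targets, spf):
    sign = -1.0 if sel[u] else 1.0
    delta = sign * costs[u]
    for j in range(indptr[u], indptr[u + 1]):
        f = feat_idx[j]
        t = targets[f]
        old_s = t - rep[f]
        if old_s < 0.0:
            old_s = 0.0
        new_s = t - (rep[f] + sign * feat_amt[j])
        if new_s < 0.0:
            new_s = 0.0
        delta += spf[f] * (new_s - old_s) / t
    return delta


@njit(inline="always")
def _apply_flip(u, sel, rep, indptr, feat_idx, feat_amt):
    sign = -1.0 if sel[u] else 1.0
    sel[u] = 1 - sel[u]
    for j in range(indptr[u], indptr[u + 1]):
        rep[feat_idx[j]] += sign * feat_amt[j]


@njit(cache=False)
def anneal_kernel(
    costs,
    indptr,
    feat_idx,
    feat_amt,
    targets,
    spf,
    n_iter,
    t_initial,
    cooling,
    improvement_passes,
    init_prob,
    seed,
):
    """Simulated annealing followed by strict-descent iterative improvement.

    Returns the selection indicator (uint8 per unit).  The best state
    visited during the annealing walk is remembered and used as the start
    of the improvement sweeps (the endpoint of the walk is a sample from
    the final-temperature distribution, not the best state seen).
    Deterministic given ``seed``: all randomness (initial selection, flip
    proposals, acceptance draws, sweep orders) comes from one seeded
    stream.
    """
    np.random.seed(seed)
    n = costs.size
    nf = targets.size
    sel = np.zeros(n, dtype=np.uint8)
    rep = np.zeros(nf, dtype=np.float64)
    score = 0.0
    for u in range(n):
        if np.random.random() < init_prob:
            sel[u] = 1
            score += costs[u]
            for j in range(indptr[u], indptr[u + 1]):
                rep[feat_idx[j]] += feat_amt[j]
    for f in range(nf):
        short = targets[f] - rep[f]
        if short > 0.0:
            score += spf[f] * short / targets[f]

    best_sel = sel.copy()
    best_score = score
    temp = t_initial
    for _ in range(n_iter):
        u = np.random.randint(0, n)
        delta = _flip_delta(u, sel, rep, costs, indptr, feat_idx, feat_amt, targets, spf)
        accept = delta < 0.0
        if not accept:
            accept = np.random.random() < np.exp(-delta / temp)
        if accept:
            _apply_flip(u, sel, rep, indptr, feat_idx, feat_amt)
            score += delta
            if score < best_score - 1e-12:
                best_score = score
                best_sel[:] = sel
        temp *= cooling

    # restart the descent from the best state of the walk
    sel = best_sel
    rep[:] = 0.0
    for u in range(n):
        if sel[u]:
            for j in range(indptr[u], indptr[u + 1]):
                rep[feat_idx[j]] += feat_amt[j]

    order = np.arange(n)
    for _ in range(improvement_passes):
        for i in range(n - 1, 0, -1):
            j = np.random.randint(0, i + 1)
            tmp = order[i]
            order[i] = order[j]
            order[j] = tmp
        changed = False
        for oi in range(n):
            u = order[oi]
            delta = _flip_delta(
                u, sel, rep, costs, indptr, feat_idx, feat_amt, targets, spf
            )
            if delta < -1e-12:
                _apply_flip(u, sel, rep, indptr, feat_idx, feat_amt)
                changed = True
        if not changed:
            break
    return sel
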