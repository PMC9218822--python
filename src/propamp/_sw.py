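"""Smith–Waterman kernels for profile–sequence and self alignment.

These numba kernels are the computational core of the iterative PSSM search:
local alignment of a position-specific scoring matrix (half-bit log-odds)
against a protein with affine gaps (a gap of length L costs
``open + L * extend``). A ``blocked`` mask lets the caller exclude already
matched residues so that successively reported matches never overlap, and a
``min_sep`` constraint restricts self-alignments to off-diagonal cells,
which is how de-novo repeat detection is implemented.

Scores are float64 half-bits; sequences are int64 index arrays (see
:mod:`propamp.alphabet`).
"""

from __future__ import annotations

import numpy as np
from numba import njit

NEG = -1e30
_EPS = 1e-6


@njit(cache=True)
def sw_fill(seq, prof, gap_open, gap_extend, min_sep, blocked, H, E, F):
    """Fill affine-gap local DP matrices; return (best, best_i, best_j).

    ``H[i, j]`` is the best local alignment score ending with seq[i-1]
    aligned to profile column j-1. ``E`` consumes sequence residues (gap in
    the profile), ``F`` consumes profile columns (gap in the sequence).
    Cells with ``i - j < min_sep`` or blocked residues are forced dead.
    """
    n = seq.shape[0]
    ncol = prof.shape[0]
    first = gap_open + gap_extend
    best = 0.0
    bi = 0
    bj = 0
    for j in range(ncol + 1):
        H[0, j] = 0.0
        E[0, j] = NEG
        F[0, j] = NEG
    for i in range(1, n + 1):
        H[i, 0] = 0.0
        E[i, 0] = NEG
        F[i, 0] = NEG
        a = seq[i - 1]
        dead_row = blocked[i - 1] != 0
        for j in range(1, ncol + 1):
            if dead_row or (i - j) < min_sep:
                H[i, j] = 0.0
                E[i, j] = NEG
                F[i, j] = NEG
                continue
            e = H[i - 1, j] - first
            if E[i - 1, j] - gap_extend > e:
                e = E[i - 1, j] - gap_extend
            f = H[i, j - 1] - first
            if F[i, j - 1] - gap_extend > f:
                f = F[i, j - 1] - gap_extend
            h = H[i - 1, j - 1] + prof[j - 1, a]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            H[i, j] = h
            E[i, j] = e
            F[i, j] = f
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj


@njit(cache=True)
def sw_traceback(seq, prof, gap_open, gap_extend, H, E, F, bi, bj):
    """Trace the optimal local path back from (bi, bj).

    Returns (ai, aj, k): the first k entries of ai/aj are 0-based
    (sequence, profile) index pairs of aligned residues, from alignment
    start to end.
    """
    n = seq.shape[0]
    ncol = prof.shape[0]
    first = gap_open + gap_extend
    cap = n + ncol + 2
    ai = np.empty(cap, dtype=np.int64)
    aj = np.empty(cap, dtype=np.int64)
    k = 0
    i = bi
    j = bj
    state = 0  # 0=H, 1=E, 2=F
    while i > 0 and j > 0:
        if state == 0:
            h = H[i, j]
            if h <= _EPS:
                break
            diag = H[i - 1, j - 1] + prof[j - 1, seq[i - 1]]
            if abs(h - diag) < _EPS:
                ai[k] = i - 1
                aj[k] = j - 1
                k += 1
                i -= 1
                j -= 1
            elif abs(h - E[i, j]) < _EPS:
                state = 1
            elif abs(h - F[i, j]) < _EPS:
                state = 2
            else:
                break
        elif state == 1:
            if abs(E[i, j] - (H[i - 1, j] - first)) < _EPS:
                state = 0
            i -= 1
        else:
            if abs(F[i, j] - (H[i, j - 1] - first)) < _EPS:
                state = 0
            j -= 1
    # reverse in place -> alignment start to end
    for t in range(k // 2):
        ai[t], ai[k - 1 - t] = ai[k - 1 - t], ai[t]
        aj[t], aj[k - 1 - t] = aj[k - 1 - t], aj[t]
    return ai, aj, k


@njit(cache=True)
def sw_score(seq, prof, gap_open, gap_extend):
    """Best local score only (rolling rows; used for shuffle nulls)."""
    n = seq.shape[0]
    ncol = prof.shape[0]
    first = gap_open + gap_extend
    hprev = np.zeros(ncol + 1)
    eprev = np.full(ncol + 1, NEG)
    hcur = np.zeros(ncol + 1)
    ecur = np.full(ncol + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        a = seq[i - 1]
        hcur[0] = 0.0
        ecur[0] = NEG
        f = NEG
        for j in range(1, ncol + 1):
            e = hprev[j] - first
            if eprev[j] - gap_extend > e:
                e = eprev[j] - gap_extend
            fn = hcur[j - 1] - first
            if f - gap_extend > fn:
                fn = f - gap_extend
            f = fn
            h = hprev[j - 1] + prof[j - 1, a]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            hcur[j] = h
            ecur[j] = e
            if h > best:
                best = h
        hprev, hcur = hcur, hprev
        eprev, ecur = ecur, eprev
    return best


@njit(cache=True)
def sw_score_batch(seqs, prof, gap_open, gap_extend):
    """Best local scores for a batch of equal-length sequences."""
    m = seqs.shape[0]
    out = np.empty(m)
    for s in range(m):
        out[s] = sw_score(seqs[s], prof, gap_open, gap_extend)
    return out


@njit(cache=True)
def sw_self_score(seq, submat, min_sep, gap_open, gap_extend):
    """Best off-diagonal local self-alignment score of one sequence.

    Scores come from ``submat[seq[j-1], seq[i-1]]``; cells closer than
    ``min_sep`` to the main diagonal are dead, so the optimum is the best
    alignment of the sequence against a copy of itself shifted by at least
    ``min_sep`` — the repeat-detection statistic.
    """
    n = seq.shape[0]
    first = gap_open + gap_extend
    hprev = np.zeros(n + 1)
    eprev = np.full(n + 1, NEG)
    hcur = np.zeros(n + 1)
    ecur = np.full(n + 1, NEG)
    best = 0.0
    for i in range(1, n + 1):
        a = seq[i - 1]
        hcur[0] = 0.0
        ecur[0] = NEG
        f = NEG
        for j in range(1, n + 1):
            if (i - j) < min_sep:
                hcur[j] = 0.0
                ecur[j] = NEG
                f = NEG
                continue
            e = hprev[j] - first
            if eprev[j] - gap_extend > e:
                e = eprev[j] - gap_extend
            fn = hcur[j - 1] - first
            if f - gap_extend > fn:
                fn = f - gap_extend
            f = fn
            h = hprev[j - 1] + submat[seq[j - 1], a]
            if e > h:
                h = e
            if f > h:
                h = f
            if h < 0.0:
                h = 0.0
            hcur[j] = h
            ecur[j] = e
            if h > best:
                best = h
        hprev, hcur = hcur, hprev
        eprev, ecur = ecur, eprev
    return best


@njit(cache=True)
def sw_self_score_batch(seqs, submat, min_sep, gap_open, gap_extend):
    m = seqs.shape[0]
    out = np.empty(m)
    for s in range(m):
        out[s] = sw_self_score(seqs[s], submat, min_sep, gap_open,
                               gap_extend)
    return out


def alloc_dp(n: int, ncol: int):
    """Allocate DP matrices for sw_fill/sw_traceback."""
    shape = (n + 1, ncol + 1)
    return np.empty(shape), np.empty(shape), np.empty(shape)
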