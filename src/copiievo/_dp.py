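"""Affine-gap dynamic-programming kernels (numba-compiled).

Both kernels work on a precomputed pairwise score matrix ``S`` (shape m x n):
for raw sequences ``S[i, j]`` is the substitution score of residue i of *a*
against residue j of *b*; for profiles it is the expected column-column score.
A gap of length k costs ``gap_open + k * gap_extend`` (both negative).
"""
from __future__ import annotations

import numpy as np
from numba import njit

_NEG = -1e30


@njit(cache=False)
def _fill_local(S, gap_open, gap_extend):
    m, n = S.shape
    H = np.zeros((m + 1, n + 1))
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    # pointers: H: 0 stop, 1 diag, 2 from F (up), 3 from E (left)
    pH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pE = np.zeros((m + 1, n + 1), dtype=np.uint8)  # 0 opened from H, 1 extended
    pF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    best = 0.0
    bi = 0
    bj = 0
    first = gap_open + gap_extend
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + first
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                pE[i, j] = 0
            else:
                E[i, j] = e_ext
                pE[i, j] = 1
            f_open = H[i - 1, j] + first
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                pF[i, j] = 0
            else:
                F[i, j] = f_ext
                pF[i, j] = 1
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            h = 0.0
            p = 0
            if diag > h:
                h = diag
                p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            pH[i, j] = p
            if h > best:
                best = h
                bi = i
                bj = j
    return best, bi, bj, H, pH, pE, pF


@njit(cache=False)
def _fill_global(S, gap_open, gap_extend):
    m, n = S.shape
    H = np.full((m + 1, n + 1), _NEG)
    E = np.full((m + 1, n + 1), _NEG)
    F = np.full((m + 1, n + 1), _NEG)
    pH = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pE = np.zeros((m + 1, n + 1), dtype=np.uint8)
    pF = np.zeros((m + 1, n + 1), dtype=np.uint8)
    first = gap_open + gap_extend
    H[0, 0] = 0.0
    for i in range(1, m + 1):
        F[i, 0] = gap_open + i * gap_extend
        H[i, 0] = F[i, 0]
        pH[i, 0] = 2
        pF[i, 0] = 0 if i == 1 else 1
    for j in range(1, n + 1):
        E[0, j] = gap_open + j * gap_extend
        H[0, j] = E[0, j]
        pH[0, j] = 3
        pE[0, j] = 0 if j == 1 else 1
    for i in range(1, m + 1):
        for j in range(1, n + 1):
            e_open = H[i, j - 1] + first
            e_ext = E[i, j - 1] + gap_extend
            if e_open >= e_ext:
                E[i, j] = e_open
                pE[i, j] = 0
            else:
                E[i, j] = e_ext
                pE[i, j] = 1
            f_open = H[i - 1, j] + first
            f_ext = F[i - 1, j] + gap_extend
            if f_open >= f_ext:
                F[i, j] = f_open
                pF[i, j] = 0
            else:
                F[i, j] = f_ext
                pF[i, j] = 1
            diag = H[i - 1, j - 1] + S[i - 1, j - 1]
            h = diag
            p = 1
            if F[i, j] > h:
                h = F[i, j]
                p = 2
            if E[i, j] > h:
                h = E[i, j]
                p = 3
            H[i, j] = h
            pH[i, j] = p
    return H[m, n], pH, pE, pF


def local_path(S: np.ndarray, gap_open: float, gap_extend: float):
    """Best local alignment over score matrix ``S``.

    Returns ``(score, pairs)`` where pairs are ``(i, j)`` with -1 marking a
    gap; deterministic tie-break: best-scoring end cell first in row-major
    order, diagonal-preferring traceback.
    """
    score, bi, bj, H, pH, pE, pF = _fill_local(
        np.ascontiguousarray(S, dtype=np.float64), float(gap_open), float(gap_extend)
    )
    pairs: list[tuple[int, int]] = []
    i, j = bi, bj
    state = 0  # 0=H 1=F 2=E
    while True:
        if state == 0:
            p = pH[i, j]
            if p == 0:
                break
            if p == 1:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = pF[i, j] == 0
            pairs.append((i - 1, -1))
            i -= 1
            state = 0 if opened else 1
        else:
            opened = pE[i, j] == 0
            pairs.append((-1, j - 1))
            j -= 1
            state = 0 if opened else 2
    pairs.reverse()
    return float(score), pairs, (i, j), (bi, bj)


def global_path(S: np.ndarray, gap_open: float, gap_extend: float):
    """Optimal global alignment over score matrix ``S`` (end gaps penalized)."""
    m, n = S.shape
    score, pH, pE, pF = _fill_global(
        np.ascontiguousarray(S, dtype=np.float64), float(gap_open), float(gap_extend)
    )
    pairs: list[tuple[int, int]] = []
    i, j = m, n
    state = 0
    while i > 0 or j > 0:
        if state == 0:
            p = pH[i, j]
            if p == 1:
                pairs.append((i - 1, j - 1))
                i -= 1
                j -= 1
            elif p == 2:
                state = 1
            else:
                state = 2
        elif state == 1:
            opened = pF[i, j] == 0
            pairs.append((i - 1, -1))
            i -= 1
            state = 0 if opened else 1
        else:
            opened = pE[i, j] == 0
            pairs.append((-1, j - 1))
            j -= 1
            state = 0 if opened else 2
    pairs.reverse()
    return float(score), pairs
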