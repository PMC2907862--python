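"""Scalar affine-gap Smith-Waterman: the reference engine.

This is a literal, row-major transcription of the affine-gap recurrence

    H(i,j) = max(0, H(i-1,j-1) + sbt(S1[i], S2[j]), E(i,j), F(i,j))
    E(i,j) = max(H(i,j-1) - rho - sigma, E(i,j-1) - sigma)
    F(i,j) = max(H(i-1,j) - rho - sigma, F(i-1,j) - sigma)

with H(i,0) = H(0,j) = E(i,0) = F(0,j) = 0, for 1 <= i <= l1, 1 <= j <= l2.
The optimal local alignment score is the maximum over H. Only H is clamped at
zero; E and F are kept as plain signed integers, exactly as the recurrence
dictates, so this engine can serve as a cell-level oracle for the vectorized
engines (which are allowed to hold stale F values).

The inner loops are compiled with numba; the Python source remains the
readable statement of the recurrence.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from numba import njit

from .scoring import ScoringScheme

__all__ = ["DPState", "sw_score", "sw_full"]

#: conservative overflow guard; scores are int64 internally but we promise
#: every reachable score fits comfortably in 32 bits
_SCORE_LIMIT = 2**31 - 1


@dataclass(frozen=True)
class DPState:
    """Full DP tables of shape (l1+1, l2+1) plus the running maximum of H."""

    H: np.ndarray
    E: np.ndarray
    F: np.ndarray
    best: int


@njit(cache=True)
def _score_kernel(q, s, sub, rho, sigma):
    l1 = q.size
    l2 = s.size
    go = rho + sigma
    h_prev = np.zeros(l2 + 1, dtype=np.int64)  # H(i-1, .)
    h_cur = np.zeros(l2 + 1, dtype=np.int64)   # H(i, .)
    f = np.zeros(l2 + 1, dtype=np.int64)       # F(i-1, .) -> F(i, .)
    best = np.int64(0)
    for i in range(1, l1 + 1):
        e = np.int64(0)  # E(i, 0)
        qi = q[i - 1]
        for j in range(1, l2 + 1):
            e = max(h_cur[j - 1] - go, e - sigma)
            f[j] = max(h_prev[j] - go, f[j] - sigma)
            h = h_prev[j - 1] + sub[qi, s[j - 1]]
            if e > h:
                h = e
            if f[j] > h:
                h = f[j]
            if h < 0:
                h = np.int64(0)
            h_cur[j] = h
            if h > best:
                best = h
        h_prev, h_cur = h_cur, h_prev
    return best


@njit(cache=True)
def _full_kernel(q, s, sub, rho, sigma):
    l1 = q.size
    l2 = s.size
    go = rho + sigma
    H = np.zeros((l1 + 1, l2 + 1), dtype=np.int64)
    E = np.zeros((l1 + 1, l2 + 1), dtype=np.int64)
    F = np.zeros((l1 + 1, l2 + 1), dtype=np.int64)
    best = np.int64(0)
    for i in range(1, l1 + 1):
        qi = q[i - 1]
        for j in range(1, l2 + 1):
            E[i, j] = max(H[i, j - 1] - go, E[i, j - 1] - sigma)
            F[i, j] = max(H[i - 1, j] - go, F[i - 1, j] - sigma)
            h = H[i - 1, j - 1] + sub[qi, s[j - 1]]
            if E[i, j] > h:
                h = E[i, j]
            if F[i, j] > h:
                h = F[i, j]
            if h < 0:
                h = np.int64(0)
            H[i, j] = h
            if h > best:
                best = h
    return H, E, F, best


def _prepare(query, subject, scheme: ScoringScheme):
    alphabet = scheme.alphabet
    q = alphabet.encode(query) if isinstance(query, str) else np.asarray(
        query, dtype=np.int64
    )
    s = alphabet.encode(subject) if isinstance(subject, str) else np.asarray(
        subject, dtype=np.int64
    )
    if q.size == 0 or s.size == 0:
        raise ValueError("sequences must be non-empty after encoding")
    # any alignment score is bounded by min(l1,l2) * max positive entry
    bound = min(q.size, s.size) * max(scheme.matrix.max_score, 0)
    if bound > _SCORE_LIMIT:
        raise OverflowError(
            f"worst-case score bound {bound} exceeds the {_SCORE_LIMIT} limit"
        )
    return q, s


def sw_score(query, subject, scheme: ScoringScheme) -> int:
    """Optimal local alignment score (max over H).

    ``query``/``subject`` may be residue strings or pre-encoded code arrays.
    """
    q, s = _prepare(query, subject, scheme)
    return int(
        _score_kernel(
            q, s, scheme.matrix.scores, scheme.gap.open, scheme.gap.extend
        )
    )


def sw_full(query, subject, scheme: ScoringScheme) -> DPState:
    """Complete H/E/F tables; ``sw_full(...).best == sw_score(...)``.

    Intended for column-level verification of the vectorized engines; uses
    O(l1*l2) memory, so keep inputs to test scale.
    """
    q, s = _prepare(query, subject, scheme)
    H, E, F, best = _full_kernel(
        q, s, scheme.matrix.scores, scheme.gap.open, scheme.gap.extend
    )
    return DPState(H=H, E=E, F=F, best=int(best))
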