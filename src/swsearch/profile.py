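"""Query profiles in sequential and striped layouts.

A query profile replaces inner-loop substitution-matrix lookups with a
precomputed table: for every alphabet residue r, ``P_r(i) = sbt(r, Q[i])``.

The *sequential* layout stores ``P_r`` in query order. The *striped* layout,
used by the vectorized engines, conceptually splits the (padded) query into
``VL`` equal segments of length ``T = ceil(l / VL)`` and interleaves them so
that SIMD lane ``v`` of vector segment ``s`` holds query position
``v * T + s`` (0-based). Lanes then process equally spaced query positions,
which pushes the vertical-gap (F) dependency out of the inner loop.

Padding positions hold the dummy residue and score 0 against everything.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scoring import SubstitutionMatrix

__all__ = [
    "SequentialProfile",
    "StripedProfile",
    "segment_count",
    "build_sequential_profile",
    "build_striped_profile",
    "striped_position_map",
    "destripe",
    "destripe_profile",
]


@dataclass(frozen=True)
class SequentialProfile:
    """Per-residue score rows in query order; shape ``(codes, padded_length)``."""

    query_length: int
    padded_length: int
    scores: np.ndarray


@dataclass(frozen=True)
class StripedProfile:
    """Per-residue score segments; shape ``(codes, T, VL)``.

    ``scores[r, s, v]`` is the substitution score of residue ``r`` against
    query position ``v * T + s`` (0 for padded tail positions).
    """

    query_length: int
    VL: int
    T: int
    scores: np.ndarray


def segment_count(l: int, VL: int) -> int:
    """Number of vector segments ``T = ceil(l / VL)``."""
    if l < 1:
        raise ValueError(f"query length must be >= 1, got {l}")
    if VL < 1:
        raise ValueError(f"lane count must be >= 1, got {VL}")
    return -(-l // VL)


def striped_position_map(l: int, VL: int) -> np.ndarray:
    """(T, VL) array of padded-query indices: entry [s, v] = v*T + s."""
    T = segment_count(l, VL)
    return np.arange(VL)[None, :] * T + np.arange(T)[:, None]


def build_sequential_profile(
    query: np.ndarray, matrix: SubstitutionMatrix, pad_to: int | None = None
) -> SequentialProfile:
    """Sequential profile: row r is ``sbt(r, Q[i])`` over query positions.

    ``pad_to`` optionally extends the query with dummy residues (used when a
    caller wants the length aligned to a lane multiple); padding is off by
    default for the scalar engine.
    """
    query = np.asarray(query, dtype=np.int64)
    if query.size == 0:
        raise ValueError("empty query")
    L = query.size if pad_to is None else max(pad_to, query.size)
    padded = np.full(L, matrix.alphabet.dummy_code, dtype=np.int64)
    padded[: query.size] = query
    return SequentialProfile(
        query_length=query.size,
        padded_length=L,
        scores=matrix.scores[:, padded],
    )


def build_striped_profile(
    query: np.ndarray, matrix: SubstitutionMatrix, VL: int
) -> StripedProfile:
    """Striped profile for lane count ``VL``; query padded to ``T * VL``."""
    query = np.asarray(query, dtype=np.int64)
    if query.size == 0:
        raise ValueError("empty query")
    T = segment_count(query.size, VL)
    padded = np.full(T * VL, matrix.alphabet.dummy_code, dtype=np.int64)
    padded[: query.size] = query
    pos = striped_position_map(query.size, VL)
    return StripedProfile(
        query_length=query.size,
        VL=VL,
        T=T,
        scores=np.ascontiguousarray(matrix.scores[:, padded[pos]]),
    )


def destripe(values: np.ndarray, query_length: int) -> np.ndarray:
    """Invert the striped mapping for one ``(T, VL)`` array of cell values.

    Returns the values in query order, truncated to the real (un-padded)
    positions. Used both for profiles and for comparing vectorized engine
    state against the scalar reference.
    """
    T, VL = values.shape
    out = np.empty(T * VL, dtype=values.dtype)
    pos = np.arange(VL)[None, :] * T + np.arange(T)[:, None]
    out[pos.ravel()] = values.ravel()
    return out[:query_length]


def destripe_profile(profile: StripedProfile) -> SequentialProfile:
    """Reconstruct the sequential profile restricted to real positions."""
    n_codes = profile.scores.shape[0]
    l = profile.query_length
    scores = np.empty((n_codes, l), dtype=profile.scores.dtype)
    for r in range(n_codes):
        scores[r] = destripe(profile.scores[r], l)
    return SequentialProfile(query_length=l, padded_length=l, scores=scores)
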