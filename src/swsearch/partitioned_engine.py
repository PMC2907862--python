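"""Partitioned vectorized Smith-Waterman with exact boundary carries.

The query is split into consecutive partitions of ``PL`` residues (``PL`` a
multiple of ``VL``; the last partition is dummy-padded). Each partition is
treated as a query in its own right — it gets its own striped profile and is
swept across the subject by the striped engine. What couples the partitions
is the vertical dependency across the partition boundary: the first row of
partition p+1 needs, per subject column j,

* the H value of partition p's last row at column j-1 (diagonal path), and
* its own F value at column j (vertical path).

Both are materialized as subject-length arrays (:class:`BoundaryCarry`).
The F entry is *not* the raw last-cell vecF — the lazy-F loop usually exits
early and leaves that stale — but the next partition's first-cell F
computed as

    F_first_next = max(H_last - open - extend, F_last - extend)

from the last cell's H and F. The last-row H is always exact after the
lazy loop, and that is what makes the carry exact regardless of how stale
the running vecF is: wherever the lazy loop skipped corrections, the
skipped F values could not beat the H path, so the H term dominates; the
striped engine additionally reconstructs the exact last-cell F from its
exact H column (see :func:`swsearch.striped_engine.last_cell_f_weights`),
which extends exactness to carries so negative they could never influence
a score. The result: the partitioned engine is score- and boundary-value-
identical to the scalar reference for every valid (PL, VL).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .profile import StripedProfile, build_striped_profile
from .scoring import GapPenalty, ScoringScheme, SubstitutionMatrix
from .striped_engine import SweepResult, striped_align

__all__ = [
    "PartitionPlan",
    "BoundaryCarry",
    "PartitionTrace",
    "partition_query",
    "carry_boundary",
    "partitioned_align",
    "partitioned_sw_score",
    "DEFAULT_PL",
    "DEFAULT_VL",
]

#: tuned defaults: 256-residue partitions on 16-lane vectors
DEFAULT_PL = 256
DEFAULT_VL = 16


@dataclass(frozen=True)
class PartitionPlan:
    """Query split into PL-length partitions, each with a striped profile."""

    query_length: int
    PL: int
    VL: int
    partitions: tuple[np.ndarray, ...]
    profiles: tuple[StripedProfile, ...]

    @property
    def n_partitions(self) -> int:
        return len(self.partitions)


@dataclass(frozen=True)
class BoundaryCarry:
    """Per-column values handed from one partition to the next.

    ``H_last[j-1]`` is the previous partition's last-row H at column j;
    ``F_first[j-1]`` is the current partition's first-row F at column j
    (both arrays have one entry per subject position).
    """

    H_last: np.ndarray
    F_first: np.ndarray

    @classmethod
    def initial(cls, subject_length: int, gap: GapPenalty) -> "BoundaryCarry":
        """Matrix-boundary carry for the first partition.

        H of the boundary row is 0 everywhere; the true first-row F is
        ``max(0 - open - extend, 0 - extend) = -extend`` at every column.
        """
        return cls(
            H_last=np.zeros(subject_length, dtype=np.int64),
            F_first=np.full(subject_length, -gap.extend, dtype=np.int64),
        )


@dataclass(frozen=True)
class PartitionTrace:
    index: int
    columns: list
    carry_out: BoundaryCarry


def partition_query(
    query: np.ndarray, PL: int, VL: int, matrix: SubstitutionMatrix
) -> PartitionPlan:
    """Split ``query`` into PL-length partitions and build their profiles."""
    query = np.asarray(query, dtype=np.int64)
    if query.size == 0:
        raise ValueError("empty query")
    if VL < 1:
        raise ValueError(f"lane count must be >= 1, got {VL}")
    if PL < VL or PL % VL != 0:
        raise ValueError(
            f"partition length {PL} must be a positive multiple of VL={VL}"
        )
    n_parts = -(-query.size // PL)
    dummy = matrix.alphabet.dummy_code
    parts = []
    for p in range(n_parts):
        chunk = np.full(PL, dummy, dtype=np.int64)
        real = query[p * PL : (p + 1) * PL]
        chunk[: real.size] = real
        parts.append(chunk)
    profiles = tuple(build_striped_profile(p, matrix, VL) for p in parts)
    return PartitionPlan(
        query_length=query.size,
        PL=PL,
        VL=VL,
        partitions=tuple(parts),
        profiles=profiles,
    )


def carry_boundary(h_last: int, f_last: int, gap: GapPenalty) -> int:
    """Next partition's first-row F from the current partition's last cell.

    ``max(H_last - open - extend, F_last - extend)``; exact even when the
    supplied F is a stale engine value, because any correction the lazy-F
    loop skipped was dominated by the H path (see module docstring).
    """
    return max(h_last - gap.open - gap.extend, f_last - gap.extend)


def partitioned_align(
    plan: PartitionPlan,
    subject: np.ndarray,
    gap: GapPenalty,
    trace: list | None = None,
    full_correction: bool = False,
) -> int:
    """Align every partition in order, threading boundary carries.

    Returns the optimal local alignment score. With ``trace`` a list, a
    :class:`PartitionTrace` (with per-column snapshots and the emitted
    carry) is appended per partition, which is how the boundary-carry
    theorem is exercised as an executable property.
    """
    subject = np.asarray(subject, dtype=np.int64)
    l2 = subject.size
    if l2 == 0:
        raise ValueError("empty subject")
    carry = BoundaryCarry.initial(l2, gap)
    sigma = gap.extend
    go = gap.open + gap.extend
    best = 0
    for p, profile in enumerate(plan.profiles):
        h_full = np.concatenate(([0], carry.H_last))  # index by column j-1
        f_full = np.concatenate(([0], carry.F_first))  # index by column j
        part_trace: list | None = [] if trace is not None else None
        sweep: SweepResult = striped_align(
            profile,
            subject,
            gap,
            h_carry=h_full,
            f_carry=f_full,
            trace=part_trace,
            full_correction=full_correction,
        )
        if sweep.best > best:
            best = sweep.best
        carry = BoundaryCarry(
            H_last=sweep.h_last[1:].copy(),
            F_first=np.maximum(sweep.h_last[1:] - go, sweep.f_last[1:] - sigma),
        )
        if trace is not None:
            trace.append(
                PartitionTrace(index=p, columns=part_trace, carry_out=carry)
            )
    return best


def partitioned_sw_score(
    query,
    subject,
    scheme: ScoringScheme,
    PL: int = DEFAULT_PL,
    VL: int = DEFAULT_VL,
) -> int:
    """Local alignment score via the partitioned engine; equals the scalar score."""
    from .scalar_engine import _prepare

    q, s = _prepare(query, subject, scheme)
    plan = partition_query(q, PL, VL, scheme.matrix)
    return partitioned_align(plan, s, scheme.gap)
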