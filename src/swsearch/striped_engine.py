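"""Striped (basic vectorized) Smith-Waterman with the lazy-F correction loop.

One column of the alignment matrix (one subject residue) is computed in two
phases on the virtualized SIMD machine:

* an **inner loop** over the ``T`` striped vector segments that computes H
  from the diagonal term, the horizontal-gap term E and a *postulated*
  vertical-gap vector ``vecF`` that is assumed not to contribute across
  segment boundaries, and

* a **lazy-F loop** that shifts the accumulated ``vecF`` one lane left
  (wrapping segment ``T-1`` back to segment ``0``, which is exactly the
  striped layout's row adjacency) and re-applies it segment by segment until
  a lane-predicate vote says no stored H can change and no larger F can
  propagate.

After finalization the de-striped H and E of the column equal the scalar
reference cell-for-cell. ``vecF`` itself carries no such guarantee — the
loop usually exits long before every F is exact — which is precisely why the
partition boundary carry recomputes the next partition's first-row F from
the (always exact) last-row H.

E ordering: E(·, j) is derived at the start of column j from the finalized
column j−1 state, so E exactness is structural and the lazy loop only ever
corrects H.

Fill values: the diagonal-H shift at column start uses the boundary (or
partition-carry) H value in lane 0; lazy-F shifts fill with 0. Fill 0 is
score-safe because H >= 0 everywhere and an F value <= 0 can neither raise
an H nor survive propagation with extend >= 1 — which is why a zero
extension penalty is rejected engine-wide.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .profile import StripedProfile, build_striped_profile
from .scoring import GapPenalty, ScoringScheme
from .simd_model import any_lanes, shift_left_lanes

__all__ = [
    "ColumnState",
    "ColumnInfo",
    "ColumnTrace",
    "SweepResult",
    "new_column_state",
    "lazy_f_predicate",
    "process_column",
    "striped_align",
    "striped_sw_score",
]

_NEG = np.int64(-(2**40))  # "no observation yet"; decays without overflow


@dataclass
class ColumnState:
    """Striped per-column engine state.

    ``vH``/``vE`` are ``(T, VL)`` arrays holding, after column j is
    finalized, the striped H(·, j) and E(·, j) values. ``best`` is the
    running maximum of H over all finalized columns.
    """

    vH: np.ndarray
    vE: np.ndarray
    best: int = 0


@dataclass(frozen=True)
class ColumnInfo:
    """Per-column facts exposed for instrumentation and boundary carries.

    ``f_last`` is the exact F of the column's last cell, reconstructed from
    the finalized (exact) H column; ``f_last_engine`` is the raw value the
    inner/lazy vecF chain happened to hold there, which is stale whenever
    the lazy loop exited early — keeping both makes the boundary-carry
    theorem observable: the carry built from ``f_last`` equals the true
    next-partition first-row F even in columns where ``f_last_engine`` is
    wrong.
    """

    lazy_visits: int         # segment visits performed by the lazy-F loop
    segments: int            # T, for classifying full vs early correction
    h_last: int              # exact H of the column's last striped cell
    f_last: int              # exact F at that cell (from the exact H column)
    f_last_engine: int       # raw (possibly stale) vecF value at that cell

    @property
    def full_correction(self) -> bool:
        """True when the lazy loop re-evaluated every vector segment."""
        return self.lazy_visits >= self.segments


@dataclass(frozen=True)
class ColumnTrace:
    column: int
    vH: np.ndarray
    vE: np.ndarray
    info: ColumnInfo


@dataclass(frozen=True)
class SweepResult:
    """Outcome of aligning one striped profile against a whole subject."""

    best: int
    h_last: np.ndarray       # (l2+1,) last-row H per column, [0] = boundary 0
    f_last: np.ndarray       # (l2+1,) exact last-cell F per column
    state: ColumnState


def new_column_state(T: int, VL: int) -> ColumnState:
    return ColumnState(
        vH=np.zeros((T, VL), dtype=np.int64),
        vE=np.zeros((T, VL), dtype=np.int64),
        best=0,
    )


def lazy_f_predicate(vecF, vecH_segment, scheme_or_gap) -> bool:
    """Vote: should the lazy-F loop keep correcting at this segment?

    Continue while any lane has ``F > max(H - open, 0)``: an H update is
    needed iff ``F > H`` (and H >= 0 everywhere), and a larger F can still
    propagate downstream iff ``F - extend > H - open - extend``, i.e.
    ``F > H - open``; with ``open >= 0`` the H-threshold covers both. The
    clamp at zero mirrors the saturating arithmetic of the hardware
    formulation: an F value <= 0 can never change any cell, and without the
    clamp the zero fill shifted into lane 0 at every wrap would keep the
    vote true forever wherever H < open.
    """
    gap = getattr(scheme_or_gap, "gap", scheme_or_gap)
    f = vecF.lanes if hasattr(vecF, "lanes") else np.asarray(vecF)
    h = (
        vecH_segment.lanes
        if hasattr(vecH_segment, "lanes")
        else np.asarray(vecH_segment)
    )
    return any_lanes(f > np.maximum(h - gap.open, 0))


def last_cell_f_weights(T: int, VL: int, gap: GapPenalty) -> np.ndarray:
    """(T, VL) weights turning an exact H column into the last cell's F.

    The vertical-gap recurrence unrolls to
    ``F(last) = max_r (H(r) - open - extend - (last-1-r) * extend)`` over
    the rows ``r`` above the last cell, plus the decayed first-row F input.
    Entry ``[s, v]`` holds ``-(open + extend + (last-1 - row) * extend)``
    for striped row ``row = v*T + s`` (an unreachable minimum for the last
    row itself, whose H does not feed its own F).
    """
    rows = (np.arange(VL)[None, :] * T + np.arange(T)[:, None]).astype(np.int64)
    last = T * VL - 1
    w = -(gap.open + gap.extend + (last - 1 - rows) * gap.extend)
    w[rows == last] = _NEG
    return w


def process_column(
    state: ColumnState,
    prof_col: np.ndarray,
    gap: GapPenalty,
    h_diag: int = 0,
    f_first: int | None = None,
    full_correction: bool = False,
    f_weights: np.ndarray | None = None,
) -> ColumnInfo:
    """Advance ``state`` by one subject position (one alignment-matrix column).

    ``prof_col`` is the ``(T, VL)`` striped profile slice for the subject
    residue. ``h_diag`` is the boundary-row H entering the diagonal path of
    the column's first striped cell (0 at the matrix boundary, the previous
    partition's last-row H otherwise); ``f_first`` likewise seeds lane 0 of
    ``vecF`` with the carried (exact) first-row F and defaults to the matrix
    boundary's true value ``-extend``.

    ``full_correction=True`` forces the lazy phase to keep sweeping whole
    wraps until a fixed point, re-evaluating every cell; it exists so tests
    can certify that the early-exit vote never changes a finalized column.
    """
    T, VL = state.vH.shape
    if prof_col.shape != (T, VL):
        raise ValueError(
            f"profile column shape {prof_col.shape} does not match state {(T, VL)}"
        )
    rho = np.int64(gap.open)
    sigma = np.int64(gap.extend)
    go = rho + sigma
    if f_first is None:
        f_first = -int(sigma)  # true F of the first matrix row
    if f_weights is None:
        f_weights = last_cell_f_weights(T, VL, gap)

    vHload = state.vH            # H(·, j-1)
    vE = state.vE                # E(·, j-1), rewritten in place to E(·, j)
    vHstore = np.empty_like(vHload)

    # diagonal input for segment 0: previous column's last segment shifted
    # one lane left; lane 0 receives the boundary/carry H value
    vH_diag = shift_left_lanes(vHload[T - 1], 1, h_diag)
    vF = np.zeros(VL, dtype=np.int64)
    vF[0] = f_first
    f_obs = _NEG

    for seg in range(T):
        if seg == T - 1:
            f_obs = vF[VL - 1]  # F estimate at the column's last cell
        e = np.maximum(vE[seg] - sigma, vHload[seg] - go)
        h = vH_diag + prof_col[seg]
        np.maximum(h, e, out=h)
        np.maximum(h, vF, out=h)
        np.maximum(h, 0, out=h)
        vH_diag = vHload[seg]
        vHstore[seg] = h
        vE[seg] = e
        vF = np.maximum(vF - sigma, h - go)

    # lazy-F phase: wrap vecF into the next stripe row and re-apply
    vF = shift_left_lanes(vF, 1, 0)
    visits = 0
    if not full_correction:
        seg = 0
        while any_lanes(vF > np.maximum(vHstore[seg] - rho, 0)):  # lazy_f_predicate
            if seg == T - 1 and vF[VL - 1] > f_obs:
                f_obs = vF[VL - 1]
            np.maximum(vHstore[seg], vF, out=vHstore[seg])
            vF = vF - sigma
            visits += 1
            seg += 1
            if seg == T:
                seg = 0
                vF = shift_left_lanes(vF, 1, 0)
    else:
        # exhaustive variant: whole wraps until nothing changes and no
        # positive F remains in flight
        while True:
            changed = False
            for seg in range(T):
                if seg == T - 1 and vF[VL - 1] > f_obs:
                    f_obs = vF[VL - 1]
                raised = vF > vHstore[seg]
                if raised.any():
                    changed = True
                    np.maximum(vHstore[seg], vF, out=vHstore[seg])
                vF = vF - sigma
                visits += 1
            vF = shift_left_lanes(vF, 1, 0)
            if not changed and not any_lanes(vF > 0):
                break

    state.vH = vHstore
    best = int(vHstore.max())
    if best > state.best:
        state.best = best
    # exact last-cell F from the exact H column plus the decayed F input;
    # the raw vecF chain cannot see negative contributions that crossed a
    # lane boundary after the vote exited, this reconstruction can
    f_last = max(
        int((vHstore + f_weights).max()), f_first - (T * VL - 1) * int(sigma)
    )
    return ColumnInfo(
        lazy_visits=visits,
        segments=T,
        h_last=int(vHstore[T - 1, VL - 1]),
        f_last=f_last,
        f_last_engine=int(f_obs),
    )


def striped_align(
    profile: StripedProfile,
    subject: np.ndarray,
    gap: GapPenalty,
    h_carry: np.ndarray | None = None,
    f_carry: np.ndarray | None = None,
    trace: list | None = None,
    full_correction: bool = False,
) -> SweepResult:
    """Sweep one striped profile across a subject sequence.

    ``h_carry``/``f_carry`` are optional ``(l2+1,)`` arrays of boundary-row
    values per column (index = column number, entry 0 = matrix boundary)
    used by the partitioned engine; absent carries mean the zero matrix
    boundary. When ``trace`` is a list, a :class:`ColumnTrace` with state
    snapshots is appended per column.
    """
    subject = np.asarray(subject, dtype=np.int64)
    l2 = subject.size
    if l2 == 0:
        raise ValueError("empty subject")
    state = new_column_state(profile.T, profile.VL)
    weights = last_cell_f_weights(profile.T, profile.VL, gap)
    h_last = np.zeros(l2 + 1, dtype=np.int64)
    f_last = np.full(l2 + 1, _NEG, dtype=np.int64)
    for j in range(1, l2 + 1):
        info = process_column(
            state,
            profile.scores[subject[j - 1]],
            gap,
            h_diag=int(h_carry[j - 1]) if h_carry is not None else 0,
            f_first=int(f_carry[j]) if f_carry is not None else None,
            full_correction=full_correction,
            f_weights=weights,
        )
        h_last[j] = info.h_last
        f_last[j] = info.f_last
        if trace is not None:
            trace.append(
                ColumnTrace(
                    column=j, vH=state.vH.copy(), vE=state.vE.copy(), info=info
                )
            )
    return SweepResult(best=state.best, h_last=h_last, f_last=f_last, state=state)


def striped_sw_score(query, subject, scheme: ScoringScheme, VL: int = 16) -> int:
    """Local alignment score via the striped engine; equals the scalar score."""
    from .scalar_engine import _prepare  # shared encoding + overflow guard

    q, s = _prepare(query, subject, scheme)
    if VL < 1:
        raise ValueError(f"lane count must be >= 1, got {VL}")
    profile = build_striped_profile(q, scheme.matrix, VL)
    return striped_align(profile, s, scheme.gap).best
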