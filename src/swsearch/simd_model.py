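"""Emulation of the virtualized SIMD lane machine.

The vectorized engines are written against a small fixed-width vector
machine: a *virtualized* SIMD vector of ``VL`` integer lanes, with lane 0 the
logical rightmost element, supporting

* leftward lane shifts with an explicit fill value (leftward = toward higher
  lane indices, per the rightmost-lane-0 convention),
* all/any lane-predicate votes (the hardware "warp vote"), and
* saturating add/subtract built from max/min against a configurable score
  range.

The emulation is sequential, so no synchronization construct is modeled, and
``VL`` may be any integer >= 1 (real hardware restricted it to sub-warp
sizes; correctness must not depend on that). With the default 32-bit score
range, saturation is unreachable at the score magnitudes this package
produces and the saturating ops reduce to plain arithmetic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "ScoreRange",
    "DEFAULT_RANGE",
    "VirtualVector",
    "shift_left",
    "shift_left_lanes",
    "all_lanes",
    "any_lanes",
    "sat_add",
    "sat_sub",
    "lane_max",
]


@dataclass(frozen=True)
class ScoreRange:
    """Closed saturation interval for lane arithmetic."""

    floor: int
    ceiling: int


DEFAULT_RANGE = ScoreRange(floor=-(2**31), ceiling=2**31 - 1)


class VirtualVector:
    """One virtualized SIMD vector: a fixed-length array of integer lanes."""

    __slots__ = ("lanes",)

    def __init__(self, lanes) -> None:
        arr = np.asarray(lanes, dtype=np.int64)
        if arr.ndim != 1:
            raise ValueError("a VirtualVector is one-dimensional")
        self.lanes = arr

    @classmethod
    def filled(cls, VL: int, value: int = 0) -> "VirtualVector":
        return cls(np.full(VL, value, dtype=np.int64))

    @property
    def VL(self) -> int:
        return self.lanes.size

    def __len__(self) -> int:
        return self.lanes.size

    def __getitem__(self, v: int) -> int:
        return int(self.lanes[v])

    def __eq__(self, other) -> bool:
        return isinstance(other, VirtualVector) and np.array_equal(
            self.lanes, other.lanes
        )

    def __repr__(self) -> str:
        return f"VirtualVector({self.lanes.tolist()})"


def _lanes(x) -> np.ndarray | int:
    return x.lanes if isinstance(x, VirtualVector) else x


def shift_left_lanes(lanes: np.ndarray, n: int, fill: int = 0) -> np.ndarray:
    """Array-level shift: out[k] = in[k-n] for k >= n, fill below.

    This is the single shift primitive; :func:`shift_left` wraps it for
    :class:`VirtualVector` operands and the engines call it on raw lane
    arrays for speed.
    """
    VL = lanes.size
    if not 0 <= n <= VL:
        raise ValueError(f"shift count {n} outside [0, {VL}]")
    out = np.empty_like(lanes)
    out[:n] = fill
    out[n:] = lanes[: VL - n]
    return out


def shift_left(v: VirtualVector, n: int, fill: int = 0) -> VirtualVector:
    """Shift ``v`` by ``n`` lanes toward higher indices, filling from lane 0."""
    return VirtualVector(shift_left_lanes(v.lanes, n, fill))


def all_lanes(pred) -> bool:
    """True iff every lane satisfies the predicate (the __all warp vote)."""
    return bool(np.all(_lanes(pred)))


def any_lanes(pred) -> bool:
    """True iff some lane satisfies the predicate (the __any warp vote)."""
    return bool(np.any(_lanes(pred)))


def _sat(values: np.ndarray, rng: ScoreRange) -> np.ndarray:
    # saturation realized with max/min, as on hardware without saturating ops
    return np.minimum(np.maximum(values, rng.floor), rng.ceiling)


def sat_add(v: VirtualVector, w, rng: ScoreRange = DEFAULT_RANGE) -> VirtualVector:
    """Lane-wise saturating addition; ``w`` may be a vector or a scalar."""
    return VirtualVector(_sat(v.lanes + _lanes(w), rng))


def sat_sub(v: VirtualVector, w, rng: ScoreRange = DEFAULT_RANGE) -> VirtualVector:
    """Lane-wise saturating subtraction; ``w`` may be a vector or a scalar."""
    return VirtualVector(_sat(v.lanes - _lanes(w), rng))


def lane_max(v: VirtualVector, w) -> VirtualVector:
    """Lane-wise maximum."""
    return VirtualVector(np.maximum(v.lanes, _lanes(w)))
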