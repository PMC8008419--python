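"""Pareto dominance, approximation sets, and exact dominated hypervolume.

All objectives are minimised.  A design ``a`` dominates ``b`` when it is
no worse in every objective and strictly better in at least one.  The
quality of a mutually nondominated set is its dominated hypervolume: the
objective-space volume dominated by the set and bounded above by a
reference point, computed exactly here for 2 and 3 objectives.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "dominates",
    "nondominated_filter",
    "ApproximationSet",
    "dominated_hypervolume",
    "hypervolume_improvement",
    "default_reference_point",
]

logger = logging.getLogger(__name__)


def dominates(a, b) -> bool:
    """Pareto dominance for minimisation: a <= b everywhere, < somewhere."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective vectors differ in length: {a.shape} vs {b.shape}")
    return bool(np.all(a <= b) and np.any(a < b))


@dataclass
class ApproximationSet:
    """A mutually nondominated set of (design, objective-vector) pairs.

    Objective-space duplicates are collapsed to the first-evaluated design;
    a point equal in all objectives to a member counts as dominated.
    """

    designs: list = field(default_factory=list)
    objectives: list = field(default_factory=list)

    def __post_init__(self) -> None:
        objs = [np.asarray(y, dtype=float) for y in self.objectives]
        for i, yi in enumerate(objs):
            for j, yj in enumerate(objs):
                if i != j and (dominates(yj, yi) or np.array_equal(yi, yj) and j < i):
                    raise ValueError("approximation set contains dominated members")
        self.objectives = objs

    def __len__(self) -> int:
        return len(self.designs)

    def __iter__(self):
        return iter(zip(self.designs, self.objectives))

    @property
    def objective_array(self) -> np.ndarray:
        if not self.objectives:
            return np.empty((0, 0))
        return np.asarray(self.objectives, dtype=float)


def nondominated_filter(points) -> ApproximationSet:
    """Retain exactly the input points not dominated by any other.

    ``points`` is an iterable of (design, objective_vector) pairs.  Ties in
    objective space keep the first-seen design; the alternates are logged.
    """
    items = [(x, np.asarray(y, dtype=float)) for x, y in points]
    kept_designs: list = []
    kept_objs: list = []
    for x, y in items:
        if any(dominates(other, y) for _, other in items if other is not y):
            continue
        dup = next((k for k, ko in enumerate(kept_objs) if np.array_equal(ko, y)), None)
        if dup is not None:
            logger.debug("objective-space duplicate %s collapsed onto first design", y)
            continue
        kept_designs.append(x)
        kept_objs.append(y)
    return ApproximationSet(kept_designs, kept_objs)


def _hv2d(points: np.ndarray, ref: np.ndarray) -> float:
    # Staircase sum: sort ascending in the first objective; each point adds
    # a rectangle from itself to the previous (better-f2) step.
    inside = points[np.all(points < ref, axis=1)]
    if inside.shape[0] < points.shape[0]:
        logger.warning(
            "%d point(s) not strictly better than the reference point contribute 0",
            points.shape[0] - inside.shape[0],
        )
    if inside.size == 0:
        return 0.0
    order = np.lexsort((inside[:, 1], inside[:, 0]))
    pts = inside[order]
    vol = 0.0
    best_f2 = ref[1]
    for f1, f2 in pts:
        if f2 < best_f2:
            vol += (ref[0] - f1) * (best_f2 - f2)
            best_f2 = f2
    return float(vol)


def _hv3d(points: np.ndarray, ref: np.ndarray) -> float:
    # Slice-sweep on the third objective: between consecutive z-levels the
    # dominated cross-section is the 2-D staircase of the active points.
    inside = points[np.all(points < ref, axis=1)]
    if inside.shape[0] < points.shape[0]:
        logger.warning(
            "%d point(s) not strictly better than the reference point contribute 0",
            points.shape[0] - inside.shape[0],
        )
    if inside.size == 0:
        return 0.0
    zs = np.unique(inside[:, 2])
    levels = np.append(zs, ref[2])
    vol = 0.0
    for lo, hi in zip(levels[:-1], levels[1:]):
        active = inside[inside[:, 2] <= lo][:, :2]
        if active.size:
            vol += _hv2d(active, ref[:2]) * (hi - lo)
    return float(vol)


def dominated_hypervolume(aset, ref) -> float:
    """Exact hypervolume dominated by a set, bounded by a reference point.

    Accepts an :class:`ApproximationSet` or an (n, B) array of objective
    vectors.  B=2 uses the sorted staircase sum, B=3 slices on the third
    objective; higher B is unsupported.  Members not strictly better than
    the reference point in every objective contribute zero (logged).
    """
    pts = aset.objective_array if isinstance(aset, ApproximationSet) else np.asarray(aset, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if pts.size == 0:
        return 0.0
    pts = np.atleast_2d(pts)
    b = pts.shape[1]
    if ref.shape != (b,):
        raise ValueError("reference point dimension mismatch")
    if b == 2:
        return _hv2d(pts, ref)
    if b == 3:
        return _hv3d(pts, ref)
    raise ValueError(f"hypervolume supported for 2 or 3 objectives, got {b}")


def hypervolume_improvement(aset, candidate, ref) -> float:
    """Hypervolume gain H(A u {candidate}) - H(A); zero for dominated candidates."""
    pts = aset.objective_array if isinstance(aset, ApproximationSet) else np.asarray(aset, dtype=float)
    cand = np.asarray(candidate, dtype=float)
    ref = np.asarray(ref, dtype=float)
    if not np.all(cand < ref):
        return 0.0
    if pts.size:
        pts = np.atleast_2d(pts)
        # Weak dominance (equal counts as dominated) => no gain; skip the sweep.
        if np.any(np.all(pts <= cand, axis=1)):
            return 0.0
        base = dominated_hypervolume(pts, ref)
        union = np.vstack([pts, cand[None, :]])
    else:
        base = 0.0
        union = cand[None, :]
    gain = dominated_hypervolume(union, ref) - base
    return float(max(gain, 0.0))


def hvi_batch_2d(front: np.ndarray, cands: np.ndarray, ref) -> np.ndarray:
    """Hypervolume improvement of many 2-D candidates against one front.

    Vectorised form used by the acquisition maximiser: the front's lower
    envelope g(u) = min{f2 : f1 <= u} is a step function, and the exclusive
    contribution of candidate (a, b) is the integral of max(g(u) - b, 0)
    over u in [a, r1].  Agrees with :func:`hypervolume_improvement`.
    """
    cands = np.atleast_2d(np.asarray(cands, dtype=float))
    ref = np.asarray(ref, dtype=float)
    front = np.asarray(front, dtype=float)
    A, B = cands[:, 0], cands[:, 1]
    if front.size == 0:
        return np.clip(ref[0] - A, 0.0, None) * np.clip(ref[1] - B, 0.0, None)
    front = np.atleast_2d(front)
    inside = front[np.all(front < ref, axis=1)]
    if inside.size == 0:
        return np.clip(ref[0] - A, 0.0, None) * np.clip(ref[1] - B, 0.0, None)
    order = np.argsort(inside[:, 0])
    fx = inside[order, 0]
    fy = np.minimum.accumulate(inside[order, 1])
    # Segment [a, fx[0]) has envelope r2; [fx[i], fx[i+1]) has fy[i].
    head = np.clip(np.minimum(fx[0], ref[0]) - A, 0.0, None) * np.clip(
        ref[1] - B, 0.0, None
    )
    starts = np.clip(fx[None, :], A[:, None], ref[0])
    ends = np.clip(np.append(fx[1:], ref[0])[None, :], A[:, None], ref[0])
    heights = np.clip(fy[None, :] - B[:, None], 0.0, None)
    return head + np.sum((ends - starts) * heights, axis=1)


def default_reference_point(objective_upper_bounds) -> np.ndarray:
    """Default reference point: per-objective upper bound scaled by 1.1.

    The specific choice only needs to be worse than any objective value the
    search can produce; hypervolumes are then comparable across methods.
    """
    ub = np.asarray(objective_upper_bounds, dtype=float)
    return ub * 1.1
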