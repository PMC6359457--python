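"""Dominance relations, Pareto extraction, and front-quality metrics.

All objectives are minimized.  The headline quality score implemented by
:func:`normalized_hypervolume` is the *mean over front points of the product
of their objective values* (smaller is better).  This is deliberately not the
classical dominated-hypervolume indicator; that one is available separately
as :func:`dominated_hypervolume`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Iterable, Mapping, Sequence

import numpy as np

__all__ = [
    "ParetoPoint",
    "ParetoArchive",
    "dominates",
    "extract_pareto",
    "normalized_hypervolume",
    "dominated_hypervolume",
    "relative_coverage",
    "combine_fronts",
]


@dataclass(frozen=True)
class ParetoPoint:
    """A candidate solution's objective vector plus an opaque payload."""

    objectives: tuple[float, ...]
    payload: Any = None

    def __post_init__(self) -> None:
        obj = tuple(float(v) for v in self.objectives)
        if not all(np.isfinite(obj)):
            raise ValueError(f"objectives must be finite, got {obj}")
        object.__setattr__(self, "objectives", obj)


@dataclass
class ParetoArchive:
    """A collection of points; flagged as a front when mutually non-dominated."""

    points: list[ParetoPoint] = field(default_factory=list)

    @property
    def n_points(self) -> int:
        return len(self.points)

    def objective_array(self) -> np.ndarray:
        """Objectives stacked as an (n_points, M) array."""
        return np.array([p.objectives for p in self.points], dtype=float)

    def is_front(self) -> bool:
        """True iff no member strictly dominates another."""
        objs = [p.objectives for p in self.points]
        return not any(
            dominates(a, b)
            for i, a in enumerate(objs)
            for j, b in enumerate(objs)
            if i != j
        )


def dominates(a: Sequence[float], b: Sequence[float], weak: bool = False) -> bool:
    """Whether objective vector ``a`` dominates ``b`` (minimization).

    Strict (default): ``a <= b`` componentwise with at least one strict
    inequality.  Weak: ``a <= b`` componentwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError(f"objective length mismatch: {a.shape} vs {b.shape}")
    if not np.all(a <= b):
        return False
    return weak or bool(np.any(a < b))


def extract_pareto(points: Iterable[ParetoPoint]) -> ParetoArchive:
    """Filter a point collection down to its non-dominated members.

    Points whose objective vectors tie exactly are all retained (their
    payloads may differ meaningfully).
    """
    pts = list(points)
    if not pts:
        raise ValueError("cannot extract a Pareto front from an empty collection")
    objs = np.array([p.objectives for p in pts], dtype=float)
    keep = _nondominated_mask(objs)
    return ParetoArchive([p for p, k in zip(pts, keep) if k])


def _nondominated_mask(objs: np.ndarray) -> np.ndarray:
    """Boolean mask of rows not strictly dominated by any other row."""
    n = objs.shape[0]
    keep = np.ones(n, dtype=bool)
    for i in range(n):
        le = np.all(objs <= objs[i], axis=1)
        lt = np.any(objs < objs[i], axis=1)
        dominated_by = le & lt
        dominated_by[i] = False
        if dominated_by.any():
            keep[i] = False
    return keep


def normalized_hypervolume(front: ParetoArchive) -> float:
    """Mean over front points of the product of their objective values.

    Smaller is better.  Note this is *not* the standard dominated-hypervolume
    indicator; see :func:`dominated_hypervolume` for that.
    """
    if front.n_points == 0:
        raise ValueError("normalized hypervolume of an empty front is undefined")
    objs = front.objective_array()
    return float(np.mean(np.prod(objs, axis=1)))


def dominated_hypervolume(front: ParetoArchive, reference: Sequence[float]) -> float:
    """Classical 2-objective dominated hypervolume w.r.t. ``reference``.

    Area (to be maximized) of the region dominated by the front and bounded
    by the reference point.  Provided for users familiar with the standard
    indicator; it is not the quality score used elsewhere in this package.
    """
    objs = front.objective_array()
    if objs.shape[1] != 2:
        raise ValueError("dominated_hypervolume supports exactly 2 objectives")
    ref = np.asarray(reference, dtype=float)
    objs = objs[_nondominated_mask(objs)]
    objs = np.unique(objs, axis=0)
    objs = objs[np.argsort(objs[:, 0])]
    area = 0.0
    prev_f2 = ref[1]
    for f1, f2 in objs:
        if f1 >= ref[0] or f2 >= prev_f2:
            continue
        area += (ref[0] - f1) * (prev_f2 - f2)
        prev_f2 = f2
    return float(area)


def relative_coverage(a: ParetoArchive, b: ParetoArchive) -> float:
    """Percentage of points in ``a`` weakly dominated by at least one point of ``b``.

    A point weakly dominates itself, so ``relative_coverage(a, a) == 100``.
    """
    if a.n_points == 0 or b.n_points == 0:
        raise ValueError("relative coverage requires two non-empty archives")
    objs_a = a.objective_array()
    objs_b = b.objective_array()
    covered = 0
    for pa in objs_a:
        if np.any(np.all(objs_b <= pa, axis=1)):
            covered += 1
    return 100.0 * covered / a.n_points


def combine_fronts(
    archives: Mapping[str, ParetoArchive],
) -> tuple[ParetoArchive, dict[str, int]]:
    """Union the named archives and keep the overall non-dominated points.

    Returns the combined front plus a per-source count of how many of its
    points survive in the combination.  Duplicate objective vectors held by
    several sources are each retained and credited to their own source.
    """
    if not archives:
        raise ValueError("need at least one archive to combine")
    names: list[str] = []
    pts: list[ParetoPoint] = []
    for name, arch in archives.items():
        for p in arch.points:
            names.append(name)
            pts.append(p)
    objs = np.array([p.objectives for p in pts], dtype=float)
    keep = _nondominated_mask(objs)
    combined = ParetoArchive([p for p, k in zip(pts, keep) if k])
    contributions = {name: 0 for name in archives}
    for name, k in zip(names, keep):
        if k:
            contributions[name] += 1
    return combined, contributions
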