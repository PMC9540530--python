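"""Convex-hull functional richness (FRic) and hull occupancy overlap.

Functional richness of an assemblage is the k-volume of the convex hull
of its species in trait space.  A hull is only defined when the
assemblage has more species than trait-space dimensions and the points
are not affinely degenerate; otherwise the metric is reported as
undefined (never as zero, which would conflate "no volume" with "volume
not measurable").  Volumes are scaled against the hull of the entire
species pool so the metric runs from 0 (no species) to 1 (all species).

Occupancy overlap between two assemblages is the fraction of the first
hull's volume inside the second, computed exactly: both hulls' facet
inequalities are pooled, an interior point of the intersection is found
as the Chebyshev center by linear programming, and the half-space
intersection polytope's volume is taken.  An infeasible or measure-zero
intersection reports 0.  No general-position jitter is applied; rank
checks handle degeneracy so results stay deterministic.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import linprog
from scipy.spatial import ConvexHull, HalfspaceIntersection, QhullError

__all__ = ["HullResult", "hull_volume", "fric_scaled", "hull_overlap_fraction"]

logger = logging.getLogger(__name__)


@dataclass
class HullResult:
    """Outcome of a hull-volume computation.

    ``defined`` is False when the point count does not exceed the
    dimension or the points are affinely degenerate; ``volume`` is only
    meaningful when ``defined`` is True.
    """

    defined: bool
    volume: float | None = None
    vertex_indices: tuple[int, ...] = field(default_factory=tuple)
    reason: str | None = None


def _affine_rank(points: np.ndarray, rtol: float = 1e-9) -> int:
    centered = points - points.mean(axis=0)
    if centered.size == 0:
        return 0
    s = np.linalg.svd(centered, compute_uv=False)
    if s.size == 0 or s[0] == 0:
        return 0
    return int(np.sum(s > rtol * s[0]))


def hull_volume(points: np.ndarray) -> HullResult:
    """k-volume of the convex hull of an n-by-k point set."""
    points = np.asarray(points, dtype=float)
    if points.ndim != 2 or points.shape[1] < 1:
        raise ValueError("points must be a 2-D array with at least one column")
    if not np.all(np.isfinite(points)):
        raise ValueError("points contain non-finite coordinates")
    n, k = points.shape
    if n <= k:
        return HullResult(False, reason=f"{n} points cannot span {k} dimensions")
    if _affine_rank(points) < k:
        return HullResult(False, reason="points are affinely degenerate")
    try:
        hull = ConvexHull(points)
    except QhullError as exc:  # rank check should prevent this
        return HullResult(False, reason=f"hull construction failed: {exc}")
    return HullResult(True, float(hull.volume), tuple(int(v) for v in hull.vertices))


def fric_scaled(subset_points: np.ndarray, global_points: np.ndarray) -> float | None:
    """Subset hull volume as a fraction of the global hull volume.

    Returns None (missing) when the subset hull is undefined; raises if
    the *global* hull is undefined, since then no scaling exists.
    """
    global_hull = hull_volume(global_points)
    if not global_hull.defined:
        raise ValueError(f"global hull undefined: {global_hull.reason}")
    sub = hull_volume(np.asarray(subset_points, dtype=float))
    if not sub.defined:
        logger.debug("subset FRic undefined: %s", sub.reason)
        return None
    return sub.volume / global_hull.volume


def _chebyshev_center(halfspaces: np.ndarray) -> tuple[np.ndarray, float] | None:
    """Largest inscribed ball center for A x + b <= 0 halfspaces."""
    A = halfspaces[:, :-1]
    b = halfspaces[:, -1]
    norms = np.linalg.norm(A, axis=1, keepdims=True)
    k = A.shape[1]
    # maximize r  s.t.  A x + r ||a|| <= -b
    c = np.zeros(k + 1)
    c[-1] = -1.0
    res = linprog(
        c,
        A_ub=np.hstack([A, norms]),
        b_ub=-b,
        bounds=[(None, None)] * k + [(0, None)],
        method="highs",
    )
    if not res.success:
        return None
    return res.x[:-1], float(res.x[-1])


def hull_overlap_fraction(points_a: np.ndarray, points_b: np.ndarray) -> float:
    """Fraction of hull(A)'s volume lying inside hull(B)."""
    res_a = hull_volume(points_a)
    res_b = hull_volume(points_b)
    for name, res in (("A", res_a), ("B", res_b)):
        if not res.defined:
            raise ValueError(f"hull {name} undefined: {res.reason}")
    hull_a = ConvexHull(np.asarray(points_a, dtype=float))
    hull_b = ConvexHull(np.asarray(points_b, dtype=float))
    halfspaces = np.vstack([hull_a.equations, hull_b.equations])
    # Shared hull vertices produce (near-)duplicate facet inequalities,
    # which destabilize the halfspace dual; deduplicate first.
    halfspaces = np.unique(halfspaces.round(12), axis=0)
    center = _chebyshev_center(halfspaces)
    if center is None:
        return 0.0
    point, radius = center
    if radius <= 1e-12:
        # Intersection is empty or measure-zero.
        return 0.0
    try:
        intersection = HalfspaceIntersection(halfspaces, point)
        inter_volume = ConvexHull(intersection.intersections).volume
    except QhullError:
        # Precision fallback: joggle the dual input.  Qhull's joggle is
        # deterministic for a given input, so results stay reproducible.
        try:
            intersection = HalfspaceIntersection(halfspaces, point, qhull_options="QJ")
            inter_volume = ConvexHull(intersection.intersections, qhull_options="QJ").volume
        except QhullError:
            logger.warning("halfspace intersection failed; reporting overlap 0")
            return 0.0
    frac = inter_volume / res_a.volume
    return float(min(max(frac, 0.0), 1.0))
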