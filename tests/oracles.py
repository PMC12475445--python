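"""Independent brute-force oracles used to verify geometry primitives.

These deliberately avoid shapely: distances are exhaustive per-segment
minima with numpy, and point-in-polygon is ray casting.
"""

from __future__ import annotations

import numpy as np


def seg_distances(points: np.ndarray, a, b) -> np.ndarray:
    """Distance from each point (n, 2) to the segment a-b."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    t = np.clip(((points - a) @ ab) / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def polyline_distances(points: np.ndarray, coords) -> np.ndarray:
    """Exhaustive per-segment minimum distance to an open polyline."""
    coords = np.asarray(coords, dtype=float)
    d = np.full(len(np.atleast_2d(points)), np.inf)
    for k in range(len(coords) - 1):
        d = np.minimum(d, seg_distances(points, coords[k], coords[k + 1]))
    return d


def ring_distances(points: np.ndarray, ring) -> np.ndarray:
    ring = np.asarray(ring, dtype=float)
    if not np.allclose(ring[0], ring[-1]):
        ring = np.vstack([ring, ring[0]])
    return polyline_distances(points, ring)


def points_in_ring(points: np.ndarray, ring) -> np.ndarray:
    """Ray-casting point-in-polygon test (boundary counts as inside-ish;
    callers pair this with distance 0 checks so the boundary is moot)."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    ring = np.asarray(ring, dtype=float)
    if np.allclose(ring[0], ring[-1]):
        ring = ring[:-1]
    x, y = points[:, 0], points[:, 1]
    inside = np.zeros(len(points), dtype=bool)
    n = len(ring)
    for i in range(n):
        x1, y1 = ring[i]
        x2, y2 = ring[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < np.where(crosses, xint, np.inf))
    return inside


def polygon_distances(points: np.ndarray, exterior, holes=()) -> np.ndarray:
    """0 inside the polygon (excluding holes), else distance to boundary."""
    points = np.asarray(points, dtype=float).reshape(-1, 2)
    d_bound = ring_distances(points, exterior)
    inside = points_in_ring(points, exterior)
    for hole in holes:
        d_bound = np.minimum(d_bound, ring_distances(points, hole))
        inside &= ~points_in_ring(points, hole)
    return np.where(inside, 0.0, d_bound)


def brute_distance(point, geometry_spec) -> float:
    """Distance to a geometry spec dict: {'type': 'point'|'polyline'|'polygon', ...}."""
    p = np.asarray(point, dtype=float).reshape(1, 2)
    kind = geometry_spec["type"]
    if kind == "point":
        return float(np.linalg.norm(p[0] - np.asarray(geometry_spec["xy"], dtype=float)))
    if kind == "polyline":
        return float(polyline_distances(p, geometry_spec["coords"])[0])
    if kind == "polygon":
        return float(
            polygon_distances(p, geometry_spec["exterior"], geometry_spec.get("holes", ()))[0]
        )
    raise ValueError(kind)


def brute_neighbors(queries, targets: dict, radius: float) -> list[set]:
    """Exhaustive strict-radius neighbor sets per query point."""
    out = []
    for q in np.asarray(queries, dtype=float).reshape(-1, 2):
        hits = {tid for tid, spec in targets.items() if brute_distance(q, spec) < radius}
        out.append(hits)
    return out


def simpson_pair_enumeration(fractions, n_bins: int) -> float:
    """Probability two distinct ROIs fall in different bins, by enumerating
    all unordered pairs."""
    from itertools import combinations

    vals = [f for f in fractions if f == f]
    bins = [min(int(f * n_bins), n_bins - 1) for f in vals]
    pairs = list(combinations(range(len(bins)), 2))
    if not pairs:
        return float("nan")
    diff = sum(1 for i, j in pairs if bins[i] != bins[j])
    return diff / len(pairs)
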