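"""Exact 2D geometry primitives.

Distances are Euclidean in the µm plane.  Neighbor queries use an STRtree for
acceleration but are contractually identical to exhaustive enumeration; the
contact predicate is a *strict* inequality (distance < radius), so a target
exactly at the radius is not a neighbor.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import shapely
from shapely.geometry import LineString, Point, Polygon
from shapely.geometry.base import BaseGeometry
from shapely.strtree import STRtree

from .io_formats import IntensityField

__all__ = [
    "LayerSet",
    "distance_to_annotation",
    "distances_to_annotation",
    "neighbors_within",
    "build_annuli",
    "assign_layers",
    "disk_mean_intensity",
    "disk_mean_intensities",
]


def _as_geometry(geometry) -> BaseGeometry:
    if isinstance(geometry, BaseGeometry):
        return geometry
    if hasattr(geometry, "geometry"):  # RegionAnnotation
        return geometry.geometry
    # bare coordinate sequence -> polyline
    return LineString(geometry)


def distance_to_annotation(point, geometry) -> float:
    """Euclidean distance from ``point`` to the nearest point of ``geometry``.

    Returns 0 for points inside or on a polygon.  Points inside a polygon
    hole get their positive distance to the hole boundary.
    """
    geom = _as_geometry(geometry)
    if geom.is_empty:
        raise ValueError("empty geometry")
    return float(geom.distance(Point(point)))


def distances_to_annotation(points, geometry) -> np.ndarray:
    """Vectorized :func:`distance_to_annotation` for an (n, 2) point array."""
    geom = _as_geometry(geometry)
    if geom.is_empty:
        raise ValueError("empty geometry")
    pts = shapely.points(np.asarray(points, dtype=float))
    return shapely.distance(pts, geom)


def _target_geometries(targets) -> tuple[list, np.ndarray]:
    """Normalize targets into (ids, shapely geometry array).

    Accepts a mapping id -> geometry-like, or an iterable of (id, geometry)
    pairs, where geometry-like is a shapely geometry, a RegionAnnotation, or
    an (x, y) coordinate pair (treated as a point).
    """
    if hasattr(targets, "items"):
        items = list(targets.items())
    else:
        items = list(targets)
    ids = [t[0] for t in items]
    geoms = []
    for _, g in items:
        if isinstance(g, BaseGeometry):
            geoms.append(g)
        elif hasattr(g, "geometry"):
            geoms.append(g.geometry)
        else:
            geoms.append(Point(g))
    return ids, np.array(geoms, dtype=object)


def neighbors_within(queries, targets, radius_um: float) -> list[dict]:
    """Per-query mapping of target id -> distance, for distance < radius.

    Parameters
    ----------
    queries
        (n, 2) array of query point coordinates in µm.
    targets
        Mapping id -> geometry, or iterable of (id, geometry) pairs; point
        coordinates are accepted as geometries.
    radius_um
        Strict search radius (> 0).

    Returns
    -------
    list of dict, one per query, each mapping the ids of all targets at
    distance strictly less than ``radius_um`` to that distance.  Empty inputs
    yield empty results.
    """
    if not radius_um > 0:
        raise ValueError("radius_um must be > 0")
    queries = np.asarray(queries, dtype=float).reshape(-1, 2)
    out: list[dict] = [dict() for _ in range(len(queries))]
    ids, geoms = _target_geometries(targets)
    if len(queries) == 0 or len(ids) == 0:
        return out
    tree = STRtree(geoms)
    qpoints = shapely.points(queries)
    qi, ti = tree.query(qpoints, predicate="dwithin", distance=radius_um)
    if len(qi):
        dists = shapely.distance(qpoints[qi], geoms[ti])
        keep = dists < radius_um  # strict: boundary equality excluded
        for q, t, d in zip(qi[keep], ti[keep], dists[keep]):
            out[int(q)][ids[int(t)]] = float(d)
    return out


@dataclass
class LayerSet:
    """Concentric outward annuli around a base (tumor) region.

    ``rings[i]`` contains the points whose distance to the base lies in
    ``[i * width_um, (i + 1) * width_um)`` up to the buffering tolerance.
    """

    base: BaseGeometry
    rings: list
    width_um: float

    @property
    def n_rings(self) -> int:
        return len(self.rings)

    @property
    def outer_boundary_um(self) -> float:
        return self.n_rings * self.width_um


def _quad_segs(radius: float, arc_tolerance_um: float) -> int:
    """Segments per quarter circle so the sagitta stays below the tolerance."""
    if arc_tolerance_um >= radius:
        return 8
    theta = math.acos(1.0 - arc_tolerance_um / radius)
    return max(8, math.ceil(math.pi / (4.0 * theta)))


def build_annuli(
    base, width_um: float, n_rings: int, arc_tolerance_um: float = 0.1
) -> LayerSet:
    """Construct ``n_rings`` disjoint annuli by successive outward offsetting."""
    if not width_um > 0:
        raise ValueError("width_um must be > 0")
    if n_rings < 1:
        raise ValueError("n_rings must be >= 1")
    geom = _as_geometry(base)
    if not geom.is_valid:
        raise ValueError("base polygon is not simple/valid")
    rings = []
    prev = geom
    for i in range(1, n_rings + 1):
        qs = _quad_segs(i * width_um, arc_tolerance_um)
        outer = geom.buffer(i * width_um, quad_segs=qs)
        rings.append(outer.difference(prev))
        prev = outer
    return LayerSet(base=geom, rings=rings, width_um=float(width_um))


def assign_layers(points, layers: LayerSet) -> np.ndarray:
    """Ring index per point by the half-open distance rule, -1 when outside.

    Points on/inside the base (distance 0) and points at or beyond the outer
    boundary get -1.  Assignment is by distance to the base, which matches
    ring membership up to buffering tolerance and is resolution-independent.
    """
    d = distances_to_annotation(points, layers.base)
    idx = np.floor(d / layers.width_um).astype(int)
    idx[(d <= 0) | (idx >= layers.n_rings)] = -1
    return idx


def _disk_pixel_values(field: IntensityField, center, radius_um: float) -> np.ndarray:
    """Values of all pixels whose centers lie within the closed disk."""
    cx, cy = float(center[0]), float(center[1])
    px = field.pixel_size_um
    x0, y0 = field.origin_um
    h, w = field.grid.shape
    # bounding box of candidate pixel indices
    j0 = max(0, int(math.floor((cx - radius_um - x0) / px - 0.5)))
    j1 = min(w - 1, int(math.ceil((cx + radius_um - x0) / px - 0.5)))
    i0 = max(0, int(math.floor((cy - radius_um - y0) / px - 0.5)))
    i1 = min(h - 1, int(math.ceil((cy + radius_um - y0) / px - 0.5)))
    if j1 < j0 or i1 < i0:
        return np.empty(0)
    xs = x0 + (np.arange(j0, j1 + 1) + 0.5) * px
    ys = y0 + (np.arange(i0, i1 + 1) + 0.5) * px
    dx2 = (xs - cx) ** 2
    dy2 = (ys - cy) ** 2
    mask = dy2[:, None] + dx2[None, :] <= radius_um**2
    return field.grid[i0 : i1 + 1, j0 : j1 + 1][mask]


def disk_mean_intensity(field: IntensityField, center, radius_um: float) -> float:
    """Mean over pixels whose centers fall within the disk, clamped at 0.

    Negative pixel values (a computational artefact in chromogen intensity
    exports) are set to zero before averaging.  Raises when the disk covers
    no pixel center.
    """
    if not radius_um > 0:
        raise ValueError("radius_um must be > 0")
    values = _disk_pixel_values(field, center, radius_um)
    if values.size == 0:
        raise ValueError("disk covers no pixel of the field")
    return float(np.maximum(values, 0.0).mean())


def disk_mean_intensities(field: IntensityField, centers, radius_um: float) -> np.ndarray:
    """Vectorized :func:`disk_mean_intensity`; NaN where a disk is off-field."""
    centers = np.asarray(centers, dtype=float).reshape(-1, 2)
    out = np.full(len(centers), np.nan)
    for k, c in enumerate(centers):
        values = _disk_pixel_values(field, c, radius_um)
        if values.size:
            out[k] = np.maximum(values, 0.0).mean()
    return out
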