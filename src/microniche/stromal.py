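"""Stromal marker quantification around tumor regions.

Concentric 15 µm layer fractions with rank tests, coexpression overlaps in a
base-positive population, disk-intensity gradients versus distance to the
invasion front (fibrosis-contact conditioned), and thresholded positive-area
fractions of intensity fields.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .io_formats import IntensityField, as_cell_frame
from .spatial import (
    LayerSet,
    assign_layers,
    disk_mean_intensities,
    distances_to_annotation,
)
from .stats import KruskalDunnResult, kruskal_dunn

__all__ = [
    "layer_fractions",
    "coexpression_overlap",
    "CoexpressionOverlap",
    "ngfr_gradient",
    "GradientProfile",
    "positive_area_fraction",
]

#: Default nuclear-circularity cut used when the stromal-enrichment filter is on.
DEFAULT_CIRCULARITY_CUT = 0.85


def layer_fractions(
    cells,
    layers: LayerSet,
    markers,
    circularity_max: float | None = None,
    exclude_positive_for: str | None = None,
) -> tuple[pd.DataFrame, dict]:
    """Per-layer positive-cell fractions plus Kruskal-Wallis/Dunn across layers.

    Cells are assigned to exactly one ring by the half-open distance rule;
    cells inside the base region or beyond the outermost ring are ignored.
    Optional pre-filters drop cells with nuclear circularity above
    ``circularity_max`` and cells positive for ``exclude_positive_for`` (the
    tumor marker).  Empty layers get NA fractions.

    Returns ``(fractions, tests)`` where ``tests`` maps marker ->
    :class:`~microniche.stats.KruskalDunnResult` on per-cell positivity
    grouped by layer.
    """
    df = as_cell_frame(cells).copy()
    if circularity_max is not None and "nuclear_circularity" in df.columns:
        df = df[~(df["nuclear_circularity"] > circularity_max)]
    if exclude_positive_for is not None:
        col = f"positive_{exclude_positive_for}"
        if col in df.columns:
            df = df[~df[col].fillna(False).astype(bool)]
    idx = assign_layers(df[["x_um", "y_um"]].to_numpy(dtype=float), layers)
    df = df[idx >= 0]
    layer_idx = idx[idx >= 0]

    rows = []
    tests: dict[str, KruskalDunnResult] = {}
    for marker in markers:
        col = f"positive_{marker}"
        if col not in df.columns:
            raise ValueError(f"missing positivity column {col!r}")
        pos = df[col].fillna(False).astype(bool).to_numpy()
        for layer in range(layers.n_rings):
            sel = pos[layer_idx == layer]
            rows.append(
                {
                    "marker": marker,
                    "layer": layer,
                    "inner_um": layer * layers.width_um,
                    "outer_um": (layer + 1) * layers.width_um,
                    "n_cells": int(len(sel)),
                    "fraction_positive": float(sel.mean()) if len(sel) else np.nan,
                }
            )
        occupied = [l for l in range(layers.n_rings) if (layer_idx == l).any()]
        if len(occupied) >= 2:
            mask = np.isin(layer_idx, occupied)
            tests[marker] = kruskal_dunn(pos[mask].astype(float), layer_idx[mask])
    return pd.DataFrame(rows), tests


@dataclass
class CoexpressionOverlap:
    base_marker: str
    n_base_positive: int
    fractions: dict
    pattern_counts: pd.DataFrame


def coexpression_overlap(cells, base_marker: str, other_markers) -> CoexpressionOverlap:
    """Coexpression within the base-marker-positive population.

    For each other marker m, ``fractions[m] = |base+ and m+| / |base+|``.
    ``pattern_counts`` lists every +/- combination of the other markers among
    base-positive cells (Venn-style); its counts partition the base-positive
    population exactly.
    """
    df = as_cell_frame(cells)
    other_markers = list(other_markers)
    for marker in [base_marker, *other_markers]:
        if f"positive_{marker}" not in df.columns:
            raise ValueError(f"missing positivity column for marker {marker!r}")
    base = df[df[f"positive_{base_marker}"].fillna(False).astype(bool)]
    n_base = len(base)
    if n_base == 0:
        import warnings

        warnings.warn("no base-positive cells", stacklevel=2)
        return CoexpressionOverlap(base_marker, 0, {m: np.nan for m in other_markers}, pd.DataFrame())
    flags = {m: base[f"positive_{m}"].fillna(False).astype(bool).to_numpy() for m in other_markers}
    fractions = {m: float(flags[m].sum()) / n_base for m in other_markers}
    patterns = pd.DataFrame(flags).groupby(other_markers).size().rename("count").reset_index()
    return CoexpressionOverlap(
        base_marker=base_marker,
        n_base_positive=n_base,
        fractions=fractions,
        pattern_counts=patterns,
    )


@dataclass
class GradientProfile:
    """Per-cell disk intensities over front distance with rolling statistics."""

    cells: pd.DataFrame  # cell_id, distance_to_front, intensity, rolling mean/sd
    window_um: float
    min_cells: int
    reference_acinar: float
    reference_adm: float
    n_excluded: int


def _rolling_stats(distances: np.ndarray, values: np.ndarray, window_um: float, min_cells: int):
    order = np.argsort(distances, kind="stable")
    ds, vs = distances[order], values[order]
    half = window_um / 2.0
    means = np.full(len(ds), np.nan)
    sds = np.full(len(ds), np.nan)
    lo = np.searchsorted(ds, ds - half, side="left")
    hi = np.searchsorted(ds, ds + half, side="right")
    for k in range(len(ds)):
        chunk = vs[lo[k] : hi[k]]
        if len(chunk) >= min_cells:
            means[k] = chunk.mean()
            sds[k] = chunk.std(ddof=1) if len(chunk) > 1 else 0.0
    inv = np.empty_like(order)
    inv[order] = np.arange(len(order))
    return means[inv], sds[inv]


def ngfr_gradient(
    tumor_cells,
    field: IntensityField,
    front,
    contacts: pd.DataFrame,
    disk_radius_um: float = 25.0,
    window_um: float = 25.0,
    min_cells: int = 20,
    reference_cells=None,
) -> GradientProfile:
    """Disk-mean stain intensity around tumor cells vs front distance.

    Only tumor cells directly interacting with fibrosis (nearest fibrosis
    distance < 20 µm per the contact table) are included.  Each included cell
    gets the mean intensity of the disk of ``disk_radius_um`` around it
    (negative pixels clamped to zero) and a rolling mean ± sample SD over
    front distance, evaluated at the cell's own distance with a window of
    ``window_um`` (NA below ``min_cells`` cells in the window).

    ``reference_cells`` (acinar/ADM cells) contribute compartment reference
    means computed the same way but without the fibrosis conditioning.
    """
    df = as_cell_frame(tumor_cells)
    df = df[df["tissue_class"] == "tumor"].copy()
    contact_map = contacts.set_index("cell_id")["contact_fibrosis"]
    included = df["cell_id"].map(contact_map).fillna(False).astype(bool)
    n_excluded = int((~included).sum())
    df = df[included]
    if df.empty:
        raise ValueError("no tumor cells with fibrosis contact; nothing to profile")
    df = df.sort_values("cell_id", kind="stable")  # order-invariant output

    coords = df[["x_um", "y_um"]].to_numpy(dtype=float)
    dist = distances_to_annotation(coords, front)
    intens = disk_mean_intensities(field, coords, disk_radius_um)
    if np.isnan(intens).any():
        raise ValueError("a disk falls entirely outside the intensity field")
    means, sds = _rolling_stats(dist, intens, window_um, min_cells)

    ref_acinar = ref_adm = np.nan
    if reference_cells is not None:
        rdf = as_cell_frame(reference_cells)
        for cls, slot in (("acinar", "acinar"), ("adm", "adm")):
            sel = rdf[rdf["tissue_class"] == cls]
            if len(sel):
                vals = disk_mean_intensities(
                    field, sel[["x_um", "y_um"]].to_numpy(dtype=float), disk_radius_um
                )
                mean = float(np.nanmean(vals))
                if slot == "acinar":
                    ref_acinar = mean
                else:
                    ref_adm = mean
    out = pd.DataFrame(
        {
            "cell_id": df["cell_id"].to_numpy(),
            "distance_to_front": dist,
            "intensity": intens,
            "rolling_mean": means,
            "rolling_sd": sds,
        }
    )
    return GradientProfile(
        cells=out,
        window_um=window_um,
        min_cells=min_cells,
        reference_acinar=ref_acinar,
        reference_adm=ref_adm,
        n_excluded=n_excluded,
    )


def positive_area_fraction(field: IntensityField, region, threshold: float) -> float:
    """Fraction of region pixels whose clamped intensity exceeds ``threshold``.

    Pixels belong to the region by center containment.  Returns NaN when the
    region contains no pixel center.
    """
    geom = region.geometry if hasattr(region, "geometry") else region
    xs, ys = field.pixel_centers()
    xmin, ymin, xmax, ymax = geom.bounds
    jsel = (xs >= xmin - field.pixel_size_um) & (xs <= xmax + field.pixel_size_um)
    isel = (ys >= ymin - field.pixel_size_um) & (ys <= ymax + field.pixel_size_um)
    if not jsel.any() or not isel.any():
        return float("nan")
    sub = field.grid[np.ix_(isel, jsel)]
    gx, gy = np.meshgrid(xs[jsel], ys[isel])
    inside = shapely.contains_xy(geom, gx.ravel(), gy.ravel()).reshape(sub.shape)
    n = int(inside.sum())
    if n == 0:
        return float("nan")
    vals = np.maximum(sub[inside], 0.0)
    return float((vals > threshold).sum()) / n
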