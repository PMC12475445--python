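"""Quantification of what tumor cells touch.

Contact calling against class-labelled regions and cells within a strict
radius (default 20 µm), per-class contact fractions, composition profiles
stratified by distance to the lobular invasion front, compartment area
fractions, exocrine composition by atrophy stage, and proximity-conditioned
normalized-intensity comparisons.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
import shapely

from .io_formats import TISSUE_CLASSES, RegionAnnotation, as_cell_frame
from .spatial import distances_to_annotation, neighbors_within
from .stats import bh_adjust, rank_sum_test

__all__ = [
    "call_contacts",
    "contact_fractions",
    "composition_by_front_distance",
    "CompositionProfile",
    "compartment_area_fractions",
    "exocrine_composition",
    "proximity_intensity_compare",
]

logger = logging.getLogger(__name__)

#: Compartment vocabulary for tumor-area annotations.
AREA_CLASSES = ("lobular", "stromal", "other")


def _normalized_class(tissue_class) -> str:
    """Map any class outside the closed vocabulary to 'other'."""
    if tissue_class in TISSUE_CLASSES:
        return tissue_class
    return "other"


def call_contacts(cells, regions, radius_um: float = 20.0) -> pd.DataFrame:
    """Per tumor cell, tissue classes with a target at distance < radius.

    Targets are class-labelled region annotations and class-labelled
    non-tumor cells; both are matched to a tumor cell's ROI (regions with an
    empty ``roi_id`` apply to every ROI).  Region classes outside the closed
    vocabulary are assigned to ``"other"``.

    Returns a wide table keyed by ``cell_id`` with ``contact_<class>``
    booleans, ``dist_<class>`` nearest distances (NaN when not in contact),
    ``distance_to_front`` (NaN when the ROI has no front), ``roi_id`` and
    ``compartment``.
    """
    df = as_cell_frame(cells)
    tumor = df[df["tissue_class"] == "tumor"].reset_index(drop=True)
    classes = list(TISSUE_CLASSES)
    columns = (
        ["cell_id", "roi_id", "compartment", "distance_to_front"]
        + [f"contact_{c}" for c in classes]
        + [f"dist_{c}" for c in classes]
    )
    if tumor.empty:
        logger.warning("no tumor cells in input; contact table is empty")
        return pd.DataFrame(columns=columns)

    region_list = list(regions)
    fronts = {r.roi_id: r for r in region_list if r.role == "front"}
    class_regions = [
        r for r in region_list if r.role != "front" and (r.tissue_class or r.role == "class-region")
    ]
    non_tumor = df[df["tissue_class"] != "tumor"]

    out_rows = []
    for roi_id, grp in tumor.groupby("roi_id", sort=True):
        coords = grp[["x_um", "y_um"]].to_numpy(dtype=float)
        targets = []
        for k, r in enumerate(class_regions):
            if r.roi_id in ("", roi_id):
                targets.append(((_normalized_class(r.tissue_class), k), r.geometry))
        nt = non_tumor[non_tumor["roi_id"] == roi_id]
        for k, row in enumerate(nt.itertuples(index=False)):
            targets.append(
                ((_normalized_class(row.tissue_class), f"cell_{k}"), (row.x_um, row.y_um))
            )
        hits = neighbors_within(coords, targets, radius_um)
        if roi_id in fronts:
            dfront = distances_to_annotation(coords, fronts[roi_id].geometry)
        else:
            dfront = np.full(len(coords), np.nan)
        for i, (cid, comp) in enumerate(zip(grp["cell_id"], grp["compartment"])):
            nearest: dict[str, float] = {}
            for (cls, _), dist in hits[i].items():
                if cls not in nearest or dist < nearest[cls]:
                    nearest[cls] = dist
            row = {
                "cell_id": cid,
                "roi_id": roi_id,
                "compartment": comp,
                "distance_to_front": float(dfront[i]) if np.isfinite(dfront[i]) else np.nan,
            }
            for c in classes:
                row[f"contact_{c}"] = c in nearest
                row[f"dist_{c}"] = nearest.get(c, np.nan)
            out_rows.append(row)
    return pd.DataFrame(out_rows, columns=columns)


def _contact_columns(table: pd.DataFrame) -> list[str]:
    return [c for c in table.columns if c.startswith("contact_")]


def contact_fractions(table: pd.DataFrame, group_by: str = "compartment") -> pd.DataFrame:
    """Per-class contact fractions and normalized contact shares per group.

    ``fraction_cells`` is the fraction of tumor cells with >= 1 contact of
    the class (these may sum above 1 across classes); ``share`` divides
    class-contact counts by the total number of (cell, class) contacts so
    shares sum to 1 within a group.
    """
    if table.empty:
        raise ValueError("contact table is empty")
    if group_by not in table.columns:
        raise ValueError(f"unknown group key {group_by!r}")
    rows = []
    for group, grp in table.groupby(group_by, sort=True):
        n_cells = len(grp)
        counts = {c[len("contact_"):]: int(grp[c].sum()) for c in _contact_columns(grp)}
        total = sum(counts.values())
        for cls, cnt in counts.items():
            rows.append(
                {
                    group_by: group,
                    "tissue_class": cls,
                    "n_cells": n_cells,
                    "n_contacting": cnt,
                    "fraction_cells": cnt / n_cells,
                    "share": cnt / total if total else np.nan,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class CompositionProfile:
    """Contact composition by distance-to-front bin.

    ``frame`` is tidy with columns bin_start, bin_end, tissue_class,
    fraction, n_cells; ``n_unbinned`` counts cells with NA front distance.
    """

    frame: pd.DataFrame
    bin_width_um: float
    n_unbinned: int


def composition_by_front_distance(
    table: pd.DataFrame, bin_width_um: float = 10.0, max_distance_um: float | None = None
) -> CompositionProfile:
    """Per-bin per-class contact fractions over distance to the front.

    Bins are half-open ``[i*w, (i+1)*w)``.  Cells with NA distance are
    excluded from the bins and counted in ``n_unbinned``.  Empty bins report
    NA fractions with n = 0.
    """
    if not bin_width_um > 0:
        raise ValueError("bin_width_um must be > 0")
    classes = [c[len("contact_"):] for c in _contact_columns(table)]
    have = table.dropna(subset=["distance_to_front"])
    n_unbinned = len(table) - len(have)
    if len(have):
        top = have["distance_to_front"].max() if max_distance_um is None else max_distance_um
        n_bins = max(1, int(np.floor(top / bin_width_um)) + 1)
    else:
        n_bins = 0
    idx = np.floor(have["distance_to_front"].to_numpy() / bin_width_um).astype(int)
    rows = []
    for b in range(n_bins):
        sel = have[idx == b]
        for cls in classes:
            rows.append(
                {
                    "bin_start": b * bin_width_um,
                    "bin_end": (b + 1) * bin_width_um,
                    "tissue_class": cls,
                    "fraction": float(sel[f"contact_{cls}"].mean()) if len(sel) else np.nan,
                    "n_cells": len(sel),
                }
            )
    frame = pd.DataFrame(
        rows, columns=["bin_start", "bin_end", "tissue_class", "fraction", "n_cells"]
    )
    return CompositionProfile(frame=frame, bin_width_um=bin_width_um, n_unbinned=n_unbinned)


def compartment_area_fractions(annotations, overlap_tolerance_um2: float = 1e-6) -> dict:
    """Area fraction per tumor-area class (lobular/stromal/other).

    Annotations of different classes must not overlap (overlap would double
    count area); overlapping pairs are reported in the error.
    """
    anns = list(annotations)
    if not anns:
        raise ValueError("no annotations given")
    for a in anns:
        label = a.tissue_class
        if label not in AREA_CLASSES:
            raise ValueError(
                f"region {a.region_id}: class {label!r} not in {AREA_CLASSES}"
            )
    offending = []
    for i in range(len(anns)):
        for j in range(i + 1, len(anns)):
            if anns[i].tissue_class == anns[j].tissue_class:
                continue
            inter = anns[i].geometry.intersection(anns[j].geometry)
            if inter.area > overlap_tolerance_um2:
                offending.append((anns[i].region_id, anns[j].region_id))
    if offending:
        raise ValueError(f"overlapping annotations of different classes: {offending}")
    areas = {c: 0.0 for c in AREA_CLASSES}
    for a in anns:
        areas[a.tissue_class] += a.geometry.area
    total = sum(areas.values())
    return {c: areas[c] / total for c in AREA_CLASSES}


def exocrine_composition(
    cells,
    lobules,
    amy_marker: str = "AMY",
    krt19_marker: str = "KRT19",
) -> pd.DataFrame:
    """Exocrine composition per lobule keyed by atrophy stage.

    Fractions of AMY+/KRT19-, AMY+/KRT19+ (double positive) and AMY-/KRT19+
    cells out of the total cell count of each lobule.  Tumor cells are
    excluded from the counts; other cell types occupy the remainder so the
    three fractions sum to <= 1.  Lobules with zero cells get NA fractions.

    Cells are assigned by a ``lobule_id`` column when present, otherwise by
    polygon containment.
    """
    df = as_cell_frame(cells)
    df = df[df["tissue_class"] != "tumor"].copy()
    lobules = list(lobules)
    if "lobule_id" not in df.columns:
        points = shapely.points(df[["x_um", "y_um"]].to_numpy(dtype=float))
        assignment = np.full(len(df), "", dtype=object)
        for lob in lobules:
            inside = shapely.covers(lob.geometry, points)
            assignment[inside & (assignment == "")] = lob.region_id
        df["lobule_id"] = assignment

    pcol_a, pcol_k = f"positive_{amy_marker}", f"positive_{krt19_marker}"
    for col in (pcol_a, pcol_k):
        if col not in df.columns:
            raise ValueError(f"missing positivity column {col!r}")
    rows = []
    for lob in lobules:
        sel = df[df["lobule_id"] == lob.region_id]
        n = len(sel)
        stage = lob.attributes.get("atrophy_stage")
        if n == 0:
            fa = fd = fk = np.nan
        else:
            amy = sel[pcol_a].fillna(False).astype(bool)
            krt = sel[pcol_k].fillna(False).astype(bool)
            fa = float((amy & ~krt).sum()) / n
            fd = float((amy & krt).sum()) / n
            fk = float((~amy & krt).sum()) / n
        rows.append(
            {
                "lobule_id": lob.region_id,
                "atrophy_stage": stage,
                "n_cells": n,
                "fraction_amy_only": fa,
                "fraction_double_positive": fd,
                "fraction_krt19_only": fk,
            }
        )
    return pd.DataFrame(rows)


def proximity_intensity_compare(
    cells,
    reference_class: str,
    markers,
    radius_um: float = 20.0,
    counterstain_col: str = "counterstain_intensity",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counterstain-normalized tumor-cell intensities near vs far from a class.

    Tumor cells are split by their nearest distance to any cell of
    ``reference_class``: strictly below ``radius_um`` ("within") vs at or
    above it ("above").  Per-cell normalized intensity is the marker
    intensity divided by the counterstain intensity; cells with zero/missing
    counterstain are excluded (count logged).  Per marker, a two-tailed
    unpaired Wilcoxon rank-sum p is reported, BH-corrected across markers.

    Returns ``(per_cell, tests)`` tidy frames.
    """
    df = as_cell_frame(cells)
    tumor = df[df["tissue_class"] == "tumor"].reset_index(drop=True)
    ref = df[df["tissue_class"] == reference_class]
    if tumor.empty:
        raise ValueError("no tumor cells in input")
    if ref.empty:
        raise ValueError(f"no cells of reference class {reference_class!r}")

    coords = tumor[["x_um", "y_um"]].to_numpy(dtype=float)
    ref_xy = ref[["x_um", "y_um"]].to_numpy(dtype=float)
    # nearest reference distance per tumor cell (exact, vectorized blocks)
    nearest = np.full(len(coords), np.inf)
    block = 512
    for s in range(0, len(coords), block):
        d2 = ((coords[s : s + block, None, :] - ref_xy[None, :, :]) ** 2).sum(axis=2)
        nearest[s : s + block] = np.sqrt(d2.min(axis=1))
    group = np.where(nearest < radius_um, "within", "above")

    counter = tumor[counterstain_col] if counterstain_col in tumor.columns else pd.Series(np.nan, index=tumor.index)
    excluded = ~(counter > 0)
    if excluded.any():
        logger.info("excluded %d cells with zero/missing counterstain", int(excluded.sum()))

    per_rows = []
    test_rows = []
    for marker in markers:
        icol = f"intensity_{marker}"
        if icol not in tumor.columns:
            raise ValueError(f"missing intensity column {icol!r}")
        ok = (~excluded) & tumor[icol].notna()
        norm = tumor.loc[ok, icol] / counter[ok]
        grp = group[ok.to_numpy()]
        for cid, g, v, d in zip(tumor.loc[ok, "cell_id"], grp, norm, nearest[ok.to_numpy()]):
            per_rows.append(
                {
                    "cell_id": cid,
                    "marker": marker,
                    "group": g,
                    "normalized_intensity": float(v),
                    "distance_to_reference": float(d),
                }
            )
        stat, p = rank_sum_test(norm[grp == "within"], norm[grp == "above"])
        test_rows.append(
            {
                "marker": marker,
                "n_within": int((grp == "within").sum()),
                "n_above": int((grp == "above").sum()),
                "median_within": float(np.median(norm[grp == "within"])) if (grp == "within").any() else np.nan,
                "median_above": float(np.median(norm[grp == "above"])) if (grp == "above").any() else np.nan,
                "statistic": stat,
                "pvalue": p,
            }
        )
    tests = pd.DataFrame(test_rows)
    tests["pvalue_bh"] = bh_adjust(tests["pvalue"])
    return pd.DataFrame(per_rows), tests
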