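"""Readers and writers for the artifact's standard file formats.

Cell tables are CSV/TSV (one row per detected cell), region annotations and
invasion fronts are GeoJSON, intensity fields are plain-text matrices with a
JSON sidecar, barcode counts are CSV, and tidy result tables are written as
CSV with a JSON manifest.

Conventions
-----------
* Coordinates are micrometres in image convention: origin top-left,
  y increases downward, 0-based continuous plane.
* Missing measurements are NA (empty CSV cells), never 0.
* Marker measurement columns are named ``intensity_<marker>`` and
  ``positive_<marker>``.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
from shapely.geometry import LineString, MultiPolygon, Polygon, mapping, shape
from shapely.geometry.base import BaseGeometry

__all__ = [
    "TISSUE_CLASSES",
    "COMPARTMENTS",
    "ATROPHY_STAGES",
    "INVASION_CATEGORIES",
    "CellRecord",
    "RegionAnnotation",
    "IntensityField",
    "BarcodeCountTable",
    "read_cell_table",
    "write_cell_table",
    "cells_to_frame",
    "frame_to_cells",
    "as_cell_frame",
    "read_cell_frame",
    "read_annotations",
    "write_annotations",
    "read_intensity_field",
    "write_intensity_field",
    "read_counts",
    "write_counts",
    "write_results",
]

#: Closed vocabulary of tissue classes for segmented cells.
TISSUE_CLASSES = (
    "tumor",
    "acinar",
    "adm",
    "duct",
    "islet",
    "fibrosis",
    "immune",
    "nerve",
    "vessel",
    "other",
)

#: Tumor-region compartment labels.
COMPARTMENTS = ("lobule", "stroma", "other", "none")

#: Five-value lobular atrophy grading vocabulary.
ATROPHY_STAGES = ("minimal", "mild", "moderate", "severe", "end-stage")

#: Lobule invasion/inflammation categories.
INVASION_CATEGORIES = ("unaffected", "inflamed", "early_invasion", "late_invasion")

#: Annotation roles.
REGION_ROLES = ("tumor_nest", "lobule", "front", "class-region", "roi_boundary")

_REQUIRED_CELL_COLUMNS = ("cell_id", "x_um", "y_um", "tissue_class")
_OPTIONAL_CELL_COLUMNS = (
    "roi_id",
    "compartment",
    "nuclear_circularity",
    "counterstain_intensity",
)


@dataclass
class CellRecord:
    """One segmented cell from a whole-slide-image export."""

    cell_id: str
    x_um: float
    y_um: float
    tissue_class: str
    roi_id: str = ""
    compartment: str = "none"
    marker_intensity: dict = field(default_factory=dict)
    marker_positive: dict = field(default_factory=dict)
    nuclear_circularity: float | None = None
    counterstain_intensity: float | None = None
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not (math.isfinite(self.x_um) and math.isfinite(self.y_um)):
            raise ValueError(f"cell {self.cell_id}: non-finite coordinates")
        if self.tissue_class not in TISSUE_CLASSES:
            raise ValueError(
                f"cell {self.cell_id}: unknown tissue_class {self.tissue_class!r}; "
                f"accepted classes are {', '.join(TISSUE_CLASSES)}"
            )
        if self.compartment not in COMPARTMENTS:
            raise ValueError(
                f"cell {self.cell_id}: unknown compartment {self.compartment!r}; "
                f"accepted values are {', '.join(COMPARTMENTS)}"
            )


@dataclass
class RegionAnnotation:
    """A polygon (tissue region) or polyline (invasion front) annotation."""

    region_id: str
    geometry: BaseGeometry
    role: str = "class-region"
    tissue_class: str | None = None
    roi_id: str = ""
    attributes: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        g = self.geometry
        if g is None or g.is_empty:
            raise ValueError(f"region {self.region_id}: empty geometry")
        if isinstance(g, Polygon):
            if not g.is_valid:
                raise ValueError(
                    f"region {self.region_id}: polygon ring is not simple "
                    "(self-intersecting or otherwise invalid)"
                )
            if g.area <= 0:
                raise ValueError(f"region {self.region_id}: polygon area must be > 0")
        elif isinstance(g, LineString):
            if len(g.coords) < 2:
                raise ValueError(
                    f"region {self.region_id}: front polyline needs >= 2 vertices"
                )
        stage = self.attributes.get("atrophy_stage")
        if stage is not None and stage not in ATROPHY_STAGES:
            raise ValueError(
                f"region {self.region_id}: unknown atrophy_stage {stage!r}; "
                f"accepted stages are {', '.join(ATROPHY_STAGES)}"
            )


@dataclass
class IntensityField:
    """Dense rasterized stain-intensity grid.

    ``grid`` is row-major with row 0 at the top; pixel (i, j) covers the
    square whose top-left corner is ``origin_um + (j, i) * pixel_size_um``.
    """

    grid: np.ndarray
    pixel_size_um: float = 0.92
    origin_um: tuple[float, float] = (0.0, 0.0)

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid, dtype=float)
        if self.grid.ndim != 2:
            raise ValueError("intensity grid must be 2-dimensional")
        if not self.pixel_size_um > 0:
            raise ValueError("pixel_size_um must be > 0")
        self.origin_um = (float(self.origin_um[0]), float(self.origin_um[1]))

    @property
    def extent_um(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) of the pixel grid in µm."""
        h, w = self.grid.shape
        x0, y0 = self.origin_um
        return (x0, y0, x0 + w * self.pixel_size_um, y0 + h * self.pixel_size_um)

    def pixel_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """1D arrays of pixel-center x (per column) and y (per row) in µm."""
        h, w = self.grid.shape
        x0, y0 = self.origin_um
        xs = x0 + (np.arange(w) + 0.5) * self.pixel_size_um
        ys = y0 + (np.arange(h) + 0.5) * self.pixel_size_um
        return xs, ys


@dataclass
class BarcodeCountTable:
    """Barcode x sample matrix of nonnegative integer read counts."""

    barcodes: list
    samples: list
    counts: np.ndarray

    def __post_init__(self) -> None:
        self.barcodes = [str(b) for b in self.barcodes]
        self.samples = [str(s) for s in self.samples]
        counts = np.asarray(self.counts)
        if counts.shape != (len(self.barcodes), len(self.samples)):
            raise ValueError("counts shape does not match barcode/sample ids")
        if np.any(counts < 0):
            raise ValueError("counts must be nonnegative")
        if not np.issubdtype(counts.dtype, np.integer):
            if not np.allclose(counts, np.round(counts)):
                raise ValueError("counts must be integral")
            counts = np.round(counts).astype(np.int64)
        self.counts = counts.astype(np.int64)
        if len(set(self.barcodes)) != len(self.barcodes):
            raise ValueError("barcode ids must be unique")
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")

    @property
    def sample_totals(self) -> np.ndarray:
        return self.counts.sum(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.counts, index=pd.Index(self.barcodes, name="barcode"), columns=self.samples
        )

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "BarcodeCountTable":
        return cls(list(frame.index), list(frame.columns), frame.to_numpy())


# ---------------------------------------------------------------------------
# cell tables
# ---------------------------------------------------------------------------


def _apply_dialect(df: pd.DataFrame, dialect: Mapping[str, str] | None) -> pd.DataFrame:
    if not dialect:
        return df
    rename = {}
    for logical, physical in dialect.items():
        if physical in df.columns:
            rename[physical] = logical
    return df.rename(columns=rename)


def _parse_bool_column(col: pd.Series) -> pd.Series:
    def conv(v):
        if pd.isna(v):
            return np.nan
        if isinstance(v, (bool, np.bool_)):
            return bool(v)
        s = str(v).strip().lower()
        if s in ("true", "1", "1.0", "yes"):
            return True
        if s in ("false", "0", "0.0", "no"):
            return False
        raise ValueError(f"cannot parse boolean value {v!r}")

    return col.map(conv)


def read_cell_frame(
    source,
    dialect: Mapping[str, str] | None = None,
    thresholds: Mapping[str, float] | None = None,
    sep: str = ",",
) -> pd.DataFrame:
    """Read a cell table into a canonical :class:`pandas.DataFrame`.

    Parameters
    ----------
    source
        Path or text stream with a header row.
    dialect
        Mapping from logical column names (``x_um`` etc.) to the physical
        column names present in the file, for foreign export schemas.
    thresholds
        Optional per-marker intensity thresholds; when ``positive_<m>`` is
        absent but ``intensity_<m>`` and a threshold are available, positivity
        is computed on load as ``intensity >= threshold``.
    """
    df = pd.read_csv(source, sep=sep, dtype={"cell_id": str}, float_precision="round_trip")
    df = _apply_dialect(df, dialect)

    for col in _REQUIRED_CELL_COLUMNS:
        if col not in df.columns:
            raise ValueError(f"cell table is missing required column {col!r}")

    for col in ("x_um", "y_um"):
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = coerced.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric coordinate in column {col!r} at data row {row + 1}"
            )
        if coerced.isna().any():
            row = int(np.flatnonzero(coerced.isna().to_numpy())[0])
            raise ValueError(f"missing coordinate in column {col!r} at data row {row + 1}")
        df[col] = coerced.astype(float)

    df["cell_id"] = df["cell_id"].astype(str)
    bad_class = ~df["tissue_class"].isin(TISSUE_CLASSES)
    if bad_class.any():
        offender = df.loc[bad_class, "tissue_class"].iloc[0]
        raise ValueError(
            f"unknown tissue_class {offender!r}; accepted classes are "
            f"{', '.join(TISSUE_CLASSES)}"
        )
    if "roi_id" not in df.columns:
        df["roi_id"] = ""
    else:
        df["roi_id"] = df["roi_id"].fillna("").astype(str)
    if "compartment" not in df.columns:
        df["compartment"] = "none"
    else:
        df["compartment"] = df["compartment"].fillna("none").astype(str)
        bad = ~df["compartment"].isin(COMPARTMENTS)
        if bad.any():
            offender = df.loc[bad, "compartment"].iloc[0]
            raise ValueError(
                f"unknown compartment {offender!r}; accepted values are "
                f"{', '.join(COMPARTMENTS)}"
            )
    for col in ("nuclear_circularity", "counterstain_intensity"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")

    positive_cols = [c for c in df.columns if c.startswith("positive_")]
    for col in positive_cols:
        df[col] = _parse_bool_column(df[col])

    if thresholds:
        for marker, thr in thresholds.items():
            icol, pcol = f"intensity_{marker}", f"positive_{marker}"
            if icol not in df.columns:
                continue
            computed = df[icol] >= thr
            if pcol in df.columns:
                have = df[pcol].notna() & df[icol].notna()
                if (df.loc[have, pcol].astype(bool) != computed[have]).any():
                    raise ValueError(
                        f"positivity for marker {marker!r} disagrees with "
                        f"intensity >= {thr}"
                    )
            else:
                df[pcol] = computed.where(df[icol].notna())
    return df


def read_cell_table(
    source,
    dialect: Mapping[str, str] | None = None,
    thresholds: Mapping[str, float] | None = None,
    sep: str = ",",
) -> list[CellRecord]:
    """Read a cell table as a list of :class:`CellRecord`."""
    return frame_to_cells(read_cell_frame(source, dialect=dialect, thresholds=thresholds, sep=sep))


def frame_to_cells(df: pd.DataFrame) -> list[CellRecord]:
    known = set(_REQUIRED_CELL_COLUMNS) | set(_OPTIONAL_CELL_COLUMNS)
    marker_i = {c: c[len("intensity_"):] for c in df.columns if c.startswith("intensity_")}
    marker_p = {c: c[len("positive_"):] for c in df.columns if c.startswith("positive_")}
    attr_cols = [c for c in df.columns if c not in known and c not in marker_i and c not in marker_p]
    cells = []
    for row in df.itertuples(index=False):
        r = row._asdict() if hasattr(row, "_asdict") else dict(zip(df.columns, row))
        intensity = {m: float(r[c]) for c, m in marker_i.items() if pd.notna(r[c])}
        positive = {m: bool(r[c]) for c, m in marker_p.items() if pd.notna(r[c])}
        circ = r.get("nuclear_circularity")
        ctr = r.get("counterstain_intensity")
        cells.append(
            CellRecord(
                cell_id=str(r["cell_id"]),
                x_um=float(r["x_um"]),
                y_um=float(r["y_um"]),
                tissue_class=r["tissue_class"],
                roi_id=str(r.get("roi_id", "")),
                compartment=str(r.get("compartment", "none")),
                marker_intensity=intensity,
                marker_positive=positive,
                nuclear_circularity=None if circ is None or pd.isna(circ) else float(circ),
                counterstain_intensity=None if ctr is None or pd.isna(ctr) else float(ctr),
                attributes={c: r[c] for c in attr_cols if pd.notna(r[c])},
            )
        )
    return cells


def cells_to_frame(cells: Iterable[CellRecord]) -> pd.DataFrame:
    rows = []
    for c in cells:
        row = {
            "cell_id": c.cell_id,
            "x_um": c.x_um,
            "y_um": c.y_um,
            "tissue_class": c.tissue_class,
            "roi_id": c.roi_id,
            "compartment": c.compartment,
            "nuclear_circularity": c.nuclear_circularity,
            "counterstain_intensity": c.counterstain_intensity,
        }
        for m, v in c.marker_intensity.items():
            row[f"intensity_{m}"] = v
        for m, v in c.marker_positive.items():
            row[f"positive_{m}"] = v
        row.update(c.attributes)
        rows.append(row)
    return pd.DataFrame(rows)


def as_cell_frame(cells) -> pd.DataFrame:
    """Accept either a canonical cell frame or a list of CellRecord."""
    if isinstance(cells, pd.DataFrame):
        return cells
    return cells_to_frame(cells)


def _canonical_cell_columns(df: pd.DataFrame) -> list[str]:
    fixed = [c for c in (*_REQUIRED_CELL_COLUMNS, *_OPTIONAL_CELL_COLUMNS) if c in df.columns]
    intens = sorted(c for c in df.columns if c.startswith("intensity_"))
    posit = sorted(c for c in df.columns if c.startswith("positive_"))
    rest = sorted(c for c in df.columns if c not in fixed and c not in intens and c not in posit)
    return fixed + intens + posit + rest


def write_cell_table(cells, dest, sep: str = ",") -> None:
    """Write cells (frame or CellRecord list) as canonical CSV (UTF-8, '.')."""
    df = as_cell_frame(cells)
    df = df[_canonical_cell_columns(df)]
    df.to_csv(dest, sep=sep, index=False, na_rep="")


# ---------------------------------------------------------------------------
# GeoJSON annotations
# ---------------------------------------------------------------------------

_ANNOTATION_PROPERTY_KEYS = ("region_id", "role", "tissue_class", "roi_id")


def read_annotations(source) -> list[RegionAnnotation]:
    """Read a GeoJSON FeatureCollection of polygons/polylines.

    Coordinates are interpreted as µm in image convention.  MultiPolygons are
    split into one annotation per part, suffixing the region id with
    ``_p<k>``.
    """
    if hasattr(source, "read"):
        doc = json.load(source)
    else:
        with open(source, encoding="utf-8") as fh:
            doc = json.load(fh)
    if doc.get("type") != "FeatureCollection":
        raise ValueError("expected a GeoJSON FeatureCollection")
    annotations: list[RegionAnnotation] = []
    for k, feature in enumerate(doc.get("features", [])):
        props = dict(feature.get("properties") or {})
        region_id = str(props.pop("region_id", f"region_{k}"))
        role = props.pop("role", "class-region")
        tissue_class = props.pop("tissue_class", None)
        roi_id = str(props.pop("roi_id", ""))
        gdict = feature["geometry"]
        if gdict.get("type") == "LineString" and len(gdict.get("coordinates", [])) < 2:
            raise ValueError(f"region {region_id}: front polyline needs >= 2 vertices")
        geom = shape(gdict)
        parts: list[tuple[str, BaseGeometry]]
        if isinstance(geom, MultiPolygon):
            parts = [(f"{region_id}_p{i}", g) for i, g in enumerate(geom.geoms)]
        else:
            parts = [(region_id, geom)]
        for part_id, g in parts:
            annotations.append(
                RegionAnnotation(
                    region_id=part_id,
                    geometry=g,
                    role=role,
                    tissue_class=tissue_class,
                    roi_id=roi_id,
                    attributes=dict(props),
                )
            )
    return annotations


def write_annotations(annotations: Sequence[RegionAnnotation], dest) -> None:
    features = []
    for ann in annotations:
        props = {"region_id": ann.region_id, "role": ann.role, "roi_id": ann.roi_id}
        if ann.tissue_class is not None:
            props["tissue_class"] = ann.tissue_class
        props.update({k: ann.attributes[k] for k in sorted(ann.attributes)})
        features.append(
            {"type": "Feature", "properties": props, "geometry": json.loads(shapely.to_geojson(ann.geometry))}
        )
    doc = {"type": "FeatureCollection", "features": features}
    if hasattr(dest, "write"):
        json.dump(doc, dest, indent=1)
    else:
        with open(dest, "w", encoding="utf-8") as fh:
            json.dump(doc, fh, indent=1)


# ---------------------------------------------------------------------------
# intensity fields
# ---------------------------------------------------------------------------


def write_intensity_field(field_: IntensityField, dest) -> None:
    """Write the grid as a text matrix plus a JSON sidecar.

    ``dest`` is the path of the matrix file; the sidecar gets ``dest + '.json'``.
    """
    dest = Path(dest)
    np.savetxt(dest, field_.grid, fmt="%.17g")
    sidecar = {
        "pixel_size_um": field_.pixel_size_um,
        "origin_um": list(field_.origin_um),
        "shape": list(field_.grid.shape),
    }
    with open(str(dest) + ".json", "w", encoding="utf-8") as fh:
        json.dump(sidecar, fh, indent=1)


def read_intensity_field(source) -> IntensityField:
    source = Path(source)
    with open(str(source) + ".json", encoding="utf-8") as fh:
        sidecar = json.load(fh)
    grid = np.loadtxt(source, ndmin=2)
    if list(grid.shape) != sidecar["shape"]:
        raise ValueError("grid shape does not match sidecar")
    return IntensityField(
        grid=grid,
        pixel_size_um=float(sidecar["pixel_size_um"]),
        origin_um=tuple(sidecar["origin_um"]),
    )


# ---------------------------------------------------------------------------
# barcode count tables
# ---------------------------------------------------------------------------


def read_counts(source, sep: str = ",") -> BarcodeCountTable:
    df = pd.read_csv(source, sep=sep, index_col=0)
    return BarcodeCountTable.from_frame(df)


def write_counts(table: BarcodeCountTable, dest, sep: str = ",") -> None:
    df = table.to_frame()
    df.index.name = "barcode"
    df.to_csv(dest, sep=sep)


# ---------------------------------------------------------------------------
# tidy result tables
# ---------------------------------------------------------------------------


def write_results(
    tables: Mapping[str, pd.DataFrame],
    dest,
    sort_keys: Mapping[str, Sequence[str]] | None = None,
    config_hash: str | None = None,
) -> dict:
    """Write one CSV per tidy table plus a JSON manifest.

    Rows are stably sorted on the declared key columns (all columns when no
    keys are declared) so repeated runs are byte-identical.  Missing values
    are written as empty cells.
    """
    dest = Path(dest)
    dest.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"files": []}
    for name in sorted(tables):
        df = tables[name]
        if len(set(df.columns)) != len(df.columns):
            raise ValueError(f"table {name!r} has duplicate column names")
        keys = list((sort_keys or {}).get(name, []))
        if not keys:
            keys = [c for c in df.columns if df[c].dtype == object or not df[c].isna().all()]
        if keys and len(df):
            df = df.sort_values(keys, kind="stable")
        path = dest / f"{name}.csv"
        df.to_csv(path, index=False, na_rep="")
        manifest["files"].append({"name": path.name, "rows": int(len(df))})
    if config_hash is not None:
        manifest["config_hash"] = config_hash
    with open(dest / "manifest.json", "w", encoding="utf-8") as fh:
        json.dump(manifest, fh, indent=1)
    return manifest


def config_digest(config_dict: Mapping) -> str:
    """Stable hash of a (nested, JSON-serializable) configuration mapping."""
    blob = json.dumps(config_dict, sort_keys=True, default=str).encode()
    return hashlib.sha256(blob).hexdigest()[:16]
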