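"""Geospatial input/output and the pipeline's core data containers.

Point samples arrive as GeoJSON or CSV (harvester exports), the study area
as a GeoJSON polygon layer, and estimated surfaces leave as GeoTIFF. All
coordinates are carried with an EPSG code; kriging stages require a
projected (metric) CRS, enforced via :mod:`geogain.crs`.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import shape as shapely_shape
from shapely.geometry.base import BaseGeometry
from shapely.ops import unary_union
import shapely

from . import crs as crs_mod
from .errors import (
    ConfigurationError,
    CRSError,
    EmptyInputError,
    EmptyRasterError,
    GeometryTypeError,
    RecordError,
)

logger = logging.getLogger(__name__)

VALID_TREATMENT_LABELS = ("T1", "T2", "T3", "T4", "T5")
NODATA = -9999.0

# coordinates closer than this (metres) count as the same harvester point
DUPLICATE_TOL = 1e-9


@dataclass(frozen=True)
class SamplePoint:
    """One georeferenced field measurement."""

    x: float
    y: float
    value: float
    treatment: str


@dataclass
class SampleSet:
    """Georeferenced point samples of one field variable across treatments.

    Coordinate, value and label columns are kept as parallel numpy arrays;
    ``treatment_labels`` preserves first-appearance order and defines the
    declared design (2-5 treatments).
    """

    x: np.ndarray
    y: np.ndarray
    values: np.ndarray
    treatments: np.ndarray
    crs: int | None
    variable_name: str = "value"
    treatment_labels: tuple[str, ...] = ()

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        self.treatments = np.asarray(self.treatments, dtype=object)
        if not self.treatment_labels:
            seen = []
            for t in self.treatments:
                if t not in seen:
                    seen.append(t)
            self.treatment_labels = tuple(seen)
        self.validate()

    def validate(self) -> None:
        n = len(self.x)
        if not (len(self.y) == len(self.values) == len(self.treatments) == n):
            raise ConfigurationError("sample columns have unequal lengths")
        if n == 0:
            raise EmptyInputError("sample set contains no points")
        if not np.all(np.isfinite(self.values)):
            bad = int(np.flatnonzero(~np.isfinite(self.values))[0])
            raise RecordError(f"non-finite variable value at record {bad}")
        labels = set(self.treatment_labels)
        if not 2 <= len(labels) <= 5:
            raise ConfigurationError(
                f"need 2-5 declared treatments, got {len(labels)}: {sorted(labels)}"
            )
        present = set(self.treatments)
        offending = present - labels
        if offending:
            raise RecordError(
                f"treatment label(s) {sorted(offending)} not among declared "
                f"labels {list(self.treatment_labels)}"
            )

    def __len__(self) -> int:
        return len(self.x)

    @property
    def points(self) -> list[SamplePoint]:
        return [
            SamplePoint(float(xi), float(yi), float(vi), str(ti))
            for xi, yi, vi, ti in zip(self.x, self.y, self.values, self.treatments)
        ]

    def subset(self, index: np.ndarray) -> "SampleSet":
        return SampleSet(
            self.x[index], self.y[index], self.values[index], self.treatments[index],
            crs=self.crs, variable_name=self.variable_name,
            treatment_labels=self.treatment_labels,
        )

    def for_treatment(self, label: str) -> "SampleSet":
        return self.subset(np.asarray([t == label for t in self.treatments]))

    def coords(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])


@dataclass
class StudyArea:
    """Polygon(s) delimiting the experimental field, with its CRS."""

    polygon: BaseGeometry
    crs: int | None

    def __post_init__(self):
        if self.polygon.is_empty or self.polygon.area <= 0:
            raise EmptyInputError("study area polygon is empty or has zero area")
        if not self.polygon.is_valid:
            self.polygon = self.polygon.buffer(0)
        if self.polygon.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryTypeError(
                f"study area must be polygonal, got {self.polygon.geom_type}"
            )


@dataclass
class RasterGrid:
    """Regular grid of estimates with georeferencing and a nodata mask.

    ``origin_x``/``origin_y`` are the coordinates of the top-left (north-west)
    grid corner; row 0 is the northernmost row. ``nodata_mask`` is True where
    a cell carries no valid estimate; masked cells never enter statistics.
    """

    origin_x: float
    origin_y: float
    pixel: float
    values: np.ndarray
    nodata_mask: np.ndarray
    crs: int | None = None

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.nodata_mask = np.asarray(self.nodata_mask, dtype=bool)
        if self.pixel <= 0:
            raise ConfigurationError(f"pixel size must be positive, got {self.pixel}")
        if self.values.ndim != 2 or self.values.shape != self.nodata_mask.shape:
            raise ConfigurationError("values and nodata_mask must share a 2-D shape")

    @property
    def nrows(self) -> int:
        return self.values.shape[0]

    @property
    def ncols(self) -> int:
        return self.values.shape[1]

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Meshgrid arrays (xs, ys) of cell-center coordinates, shape nrows x ncols."""
        xs = self.origin_x + (np.arange(self.ncols) + 0.5) * self.pixel
        ys = self.origin_y - (np.arange(self.nrows) + 0.5) * self.pixel
        return np.meshgrid(xs, ys)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point plus an in-bounds flag.

        Cells are half-open: x in [x0, x0+pixel); y in (ytop-pixel, ytop].
        """
        x = np.atleast_1d(np.asarray(x, dtype=float))
        y = np.atleast_1d(np.asarray(y, dtype=float))
        col = np.floor((x - self.origin_x) / self.pixel).astype(int)
        row = np.floor((self.origin_y - y) / self.pixel).astype(int)
        # top edge belongs to row 0
        row = np.where((self.origin_y - y) == 0.0, 0, row)
        inside = (col >= 0) & (col < self.ncols) & (row >= 0) & (row < self.nrows)
        return row, col, inside

    def valid_values(self) -> np.ndarray:
        return self.values[~self.nodata_mask]

    def copy_with(self, values: np.ndarray, mask: np.ndarray) -> "RasterGrid":
        return RasterGrid(self.origin_x, self.origin_y, self.pixel,
                          values, mask, crs=self.crs)

    def same_grid(self, other: "RasterGrid", tol: float = 1e-9) -> bool:
        return (
            self.values.shape == other.values.shape
            and abs(self.origin_x - other.origin_x) <= tol
            and abs(self.origin_y - other.origin_y) <= tol
            and abs(self.pixel - other.pixel) <= tol
            and self.crs == other.crs
        )


# ---------------------------------------------------------------------------
# readers


def _merge_duplicates(x, y, v, t):
    """Average values of points sharing coordinates within DUPLICATE_TOL.

    The merge is performed within each treatment label: identical point sets
    overlaid under different labels are a legitimate null-experiment design
    and must stay separate.
    """
    groups: dict = {}
    for i, (xi, yi, ti) in enumerate(zip(x, y, t)):
        k = (ti, round(xi / DUPLICATE_TOL), round(yi / DUPLICATE_TOL))
        groups.setdefault(k, []).append(i)
    if len(groups) == len(x):
        return x, y, v, t
    logger.info("merged %d duplicate-coordinate point(s) by averaging",
                len(x) - len(groups))
    # keep first occurrence order, average values within each group
    firsts = sorted(groups.values(), key=lambda idx: idx[0])
    keep = np.asarray([idx[0] for idx in firsts])
    vals = np.asarray([float(np.mean(v[idx])) for idx in firsts])
    return x[keep], y[keep], vals, t[keep]


def _finalize_samples(df: pd.DataFrame, variable_field: str, treatment_field: str,
                      x_field: str, y_field: str, crs, variable_name=None) -> SampleSet:
    for f in (variable_field, treatment_field, x_field, y_field):
        if f not in df.columns:
            raise ConfigurationError(f"required field '{f}' not found in input "
                                     f"(available: {list(df.columns)})")
    if len(df) == 0:
        raise EmptyInputError("input layer contains zero features")
    vals = pd.to_numeric(df[variable_field], errors="coerce").to_numpy(dtype=float)
    bad = np.flatnonzero(~np.isfinite(vals))
    if bad.size:
        raise RecordError(
            f"non-numeric variable value in field '{variable_field}' at feature "
            f"index {int(bad[0])}: {df[variable_field].iloc[int(bad[0])]!r}"
        )
    trt = np.asarray([str(s).strip() for s in df[treatment_field]], dtype=object)
    x = df[x_field].to_numpy(dtype=float)
    y = df[y_field].to_numpy(dtype=float)
    x, y, vals, trt = _merge_duplicates(x, y, vals, trt)
    return SampleSet(x, y, vals, trt, crs=crs,
                     variable_name=variable_name or variable_field)


def _geojson_epsg(doc: dict) -> int | None:
    crs_member = doc.get("crs")
    if crs_member is None:
        return 4326  # RFC 7946 default
    name = crs_member.get("properties", {}).get("name", "")
    if "EPSG" in name.upper():
        try:
            return int(name.upper().split("EPSG")[-1].strip(":/ "))
        except ValueError:
            pass
    return None


def read_point_samples(path, variable_field: str, treatment_field: str, *,
                       x_field: str = "x", y_field: str = "y",
                       crs: int | None = None) -> SampleSet:
    """Read georeferenced point samples from GeoJSON or CSV.

    GeoJSON carries its own CRS (legacy ``crs`` member, else WGS84); CSV
    needs explicit ``x_field``/``y_field`` columns and a ``crs`` EPSG code.
    Exact duplicate coordinates within a treatment are merged by averaging.
    """
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    if path.suffix.lower() in (".csv", ".txt"):
        df = pd.read_csv(path)
        return _finalize_samples(df, variable_field, treatment_field,
                                 x_field, y_field, crs)
    doc = json.loads(path.read_text())
    feats = doc.get("features", [])
    if not feats:
        raise EmptyInputError(f"no features in {path}")
    rows = []
    for i, f in enumerate(feats):
        geom = f.get("geometry") or {}
        if geom.get("type") != "Point":
            raise GeometryTypeError(
                f"feature {i} has geometry {geom.get('type')}, expected Point")
        gx, gy = geom["coordinates"][:2]
        props = f.get("properties", {})
        rows.append({**props, "__x__": gx, "__y__": gy})
    df = pd.DataFrame(rows)
    file_crs = crs if crs is not None else _geojson_epsg(doc)
    return _finalize_samples(df, variable_field, treatment_field,
                             "__x__", "__y__", file_crs)


def read_study_area(path, *, crs: int | None = None) -> StudyArea:
    """Read the study-area polygon layer (GeoJSON); multiple features are unioned."""
    path = Path(path)
    if not path.exists():
        raise ConfigurationError(f"input file not found: {path}")
    doc = json.loads(path.read_text())
    if doc.get("type") == "FeatureCollection":
        geoms = [shapely_shape(f["geometry"]) for f in doc.get("features", [])]
    elif doc.get("type") == "Feature":
        geoms = [shapely_shape(doc["geometry"])]
    else:
        geoms = [shapely_shape(doc)]
    if not geoms:
        raise EmptyInputError(f"no polygon features in {path}")
    for g in geoms:
        if g.geom_type not in ("Polygon", "MultiPolygon"):
            raise GeometryTypeError(
                f"study area layer contains {g.geom_type}, expected Polygon")
    file_crs = crs if crs is not None else _geojson_epsg(doc)
    return StudyArea(unary_union(geoms), crs=file_crs)


# ---------------------------------------------------------------------------
# reprojection


def reproject_samples(s: SampleSet, target_crs: int) -> SampleSet:
    """Reproject sample coordinates into a projected (metric) CRS."""
    if crs_mod.is_geographic(target_crs):
        raise CRSError(
            f"target EPSG:{target_crs} is geographic (degrees); kriging requires "
            "a projected metric CRS")
    x, y = crs_mod.transform(s.x, s.y, s.crs, target_crs)
    return SampleSet(x, y, s.values.copy(), s.treatments.copy(), crs=int(target_crs),
                     variable_name=s.variable_name,
                     treatment_labels=s.treatment_labels)


def reproject_area(a: StudyArea, target_crs: int) -> StudyArea:
    if crs_mod.is_geographic(target_crs):
        raise CRSError(
            f"target EPSG:{target_crs} is geographic (degrees); kriging requires "
            "a projected metric CRS")
    if a.crs is None:
        raise CRSError("study area CRS unknown; declare an explicit EPSG code")
    if int(a.crs) == int(target_crs):
        return StudyArea(a.polygon, crs=int(target_crs))
    geom = shapely.transform(
        a.polygon,
        lambda pts: np.column_stack(
            crs_mod.transform(pts[:, 0], pts[:, 1], a.crs, target_crs)),
    )
    return StudyArea(geom, crs=int(target_crs))


# ---------------------------------------------------------------------------
# raster I/O (GeoTIFF via hand-assembled GeoTIFF tags)

_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GDAL_NODATA = 42113


def write_raster(g: RasterGrid, path) -> None:
    """Write a grid as a single-band float64 GeoTIFF, nodata −9999.

    Round-trip through :func:`read_raster` reproduces values bit-exactly and
    the mask exactly (valid cells must therefore never hold exactly −9999).
    """
    path = Path(path)
    data = np.where(g.nodata_mask, NODATA, g.values).astype(np.float64)
    epsg = int(g.crs) if g.crs is not None else 32767  # user-defined
    model_type = 2 if (g.crs is not None and crs_mod.is_geographic(g.crs)) else 1
    cs_key = 2048 if model_type == 2 else 3072
    geokeys = (1, 1, 0, 3,
               1024, 0, 1, model_type,
               1025, 0, 1, 1,          # RasterPixelIsArea
               cs_key, 0, 1, epsg)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (g.pixel, g.pixel, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, g.origin_x, g.origin_y, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(geokeys), geokeys),
        (_TAG_GDAL_NODATA, "s", 0, str(NODATA)),
    ]
    tifffile.imwrite(path, data, extratags=extratags)


def read_raster(path) -> RasterGrid:
    """Read a GeoTIFF written by :func:`write_raster`."""
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        data = page.asarray().astype(np.float64)
        tags = page.tags
        scale = tags[_TAG_MODEL_PIXEL_SCALE].value
        tie = tags[_TAG_MODEL_TIEPOINT].value
        keys = tags[_TAG_GEO_KEY_DIRECTORY].value
        nodata = float(tags[_TAG_GDAL_NODATA].value) if _TAG_GDAL_NODATA in tags else NODATA
    epsg = None
    keys = list(keys)
    for i in range(4, len(keys), 4):
        if keys[i] in (2048, 3072) and keys[i + 3] != 32767:
            epsg = int(keys[i + 3])
    mask = data == nodata
    return RasterGrid(origin_x=float(tie[3]), origin_y=float(tie[4]),
                      pixel=float(scale[0]), values=data, nodata_mask=mask,
                      crs=epsg)


# ---------------------------------------------------------------------------
# HTML gain report

_REPORT_TEMPLATE = """\
<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Statistics of Gain</title>
<style>
 body { font-family: sans-serif; margin: 2em; }
 table { border-collapse: collapse; margin-top: 1em; }
 th, td { border: 1px solid #888; padding: 0.4em 0.8em; text-align: right; }
 th { background: #eee; }
 td:first-child { text-align: left; }
 .meta { color: #444; font-size: 0.9em; }
</style>
</head>
<body>
<h1>Statistics of Gain</h1>
{% if meta %}
<p class="meta">
{% for k, v in meta.items() %}{{ k }}: {{ v }}{% if not loop.last %} &middot; {% endif %}{% endfor %}
</p>
{% endif %}
<table>
<tr><th>Comparison</th><th>Min</th><th>Max</th><th>Sum</th><th>Mean</th>
<th>Std</th><th>Valid cells</th></tr>
{% for label, s in stats.items() %}
<tr><td>{{ label }}</td><td>{{ s.minimum|round(6) }}</td><td>{{ s.maximum|round(6) }}</td>
<td>{{ s.sum|round(6) }}</td><td>{{ s.mean|round(6) }}</td><td>{{ s.std|round(6) }}</td>
<td>{{ s.n_valid }}</td></tr>
{% endfor %}
</table>
</body>
</html>
"""


def write_gain_report(stats: Mapping[str, object], meta: Mapping[str, object],
                      path) -> None:
    """Write the per-comparison gain statistics as a self-contained HTML table.

    ``stats`` maps a comparison label (e.g. ``"T2 - T1"``) to an object with
    minimum/maximum/sum/mean/std/n_valid attributes.
    """
    from jinja2 import Template

    if not stats:
        raise EmptyInputError("gain report requires at least one statistics entry")
    html = Template(_REPORT_TEMPLATE).render(stats=dict(stats), meta=dict(meta or {}))
    Path(path).write_text(html)
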