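"""Grid model and single-band GeoTIFF I/O shared by every pipeline stage.

The grid is a projected, equal-area raster of square cells: row 0 is the top
row, cell ``(r, c)`` covers the half-open square
``[x_origin + c*s, x_origin + (c+1)*s) x (y_origin - (r+1)*s, y_origin - r*s]``
with ``s = cell_size_m`` in meters.  Inputs on geographic (degree) grids must
be projected before use; no reprojection is performed here.

Nodata conventions (in memory):

* float-valued kinds (``friction``, ``population``) use ``NaN`` for nodata;
* ``travel_time`` uses ``+inf`` for unreachable-or-nodata cells (written to
  disk as the nodata sentinel, restored as ``+inf`` on read);
* integer kinds (``zone``, ``mask``, ``heatmap_class``) use the integer
  ``spec.nodata`` code directly.
"""

from __future__ import annotations

import math
import os
from dataclasses import dataclass, field, replace
from typing import Iterator

import numpy as np
import tifffile

__all__ = [
    "RASTER_KINDS",
    "GridSpec",
    "Raster",
    "RasterValidationError",
    "AlignmentError",
    "align_check",
    "require_aligned",
    "read_raster",
    "write_raster",
]

RASTER_KINDS = frozenset(
    {"friction", "population", "travel_time", "zone", "mask", "heatmap_class"}
)

_FLOAT_KINDS = frozenset({"friction", "population", "travel_time"})
_INT_KINDS = RASTER_KINDS - _FLOAT_KINDS

# TIFF tag codes used to carry georeferencing
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_ASCII = 34737
_TAG_GDAL_NODATA = 42113


class RasterValidationError(ValueError):
    """A raster violates the invariants of its declared kind."""


class AlignmentError(ValueError):
    """Two rasters that must share a grid do not."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of a raster grid: shape, cell size, upper-left origin."""

    n_rows: int
    n_cols: int
    cell_size_m: float
    x_origin: float = 0.0
    y_origin: float = 0.0
    crs_id: str = "LOCAL"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError(f"grid shape must be >= 1x1, got {self.n_rows}x{self.n_cols}")
        if not (self.cell_size_m > 0):
            raise ValueError(f"cell_size_m must be > 0, got {self.cell_size_m}")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    def cell_center(self, row: int, col: int) -> tuple[float, float]:
        """World coordinates of the center of cell ``(row, col)``."""
        s = self.cell_size_m
        return (self.x_origin + (col + 0.5) * s, self.y_origin - (row + 0.5) * s)

    def world_to_cell(self, x: float, y: float) -> tuple[int, int]:
        """Cell index containing world point ``(x, y)`` (may be out of bounds)."""
        s = self.cell_size_m
        col = math.floor((x - self.x_origin) / s)
        row = math.floor((self.y_origin - y) / s)
        return (int(row), int(col))

    def contains_cell(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def aligned_with(self, other: "GridSpec") -> bool:
        """True iff both grids describe the same cells (nodata excluded)."""
        return (
            self.n_rows == other.n_rows
            and self.n_cols == other.n_cols
            and math.isclose(self.cell_size_m, other.cell_size_m, rel_tol=1e-9, abs_tol=1e-9)
            and math.isclose(self.x_origin, other.x_origin, rel_tol=1e-9, abs_tol=1e-6)
            and math.isclose(self.y_origin, other.y_origin, rel_tol=1e-9, abs_tol=1e-6)
            and self.crs_id == other.crs_id
        )


@dataclass
class Raster:
    """A single-band raster: a :class:`GridSpec` plus a value array and kind."""

    spec: GridSpec
    values: np.ndarray
    kind: str

    def __post_init__(self) -> None:
        if self.kind not in RASTER_KINDS:
            raise ValueError(f"unknown raster kind {self.kind!r}; expected one of {sorted(RASTER_KINDS)}")
        values = np.asarray(self.values)
        if values.ndim != 2:
            raise RasterValidationError(f"raster values must be 2-D, got ndim={values.ndim}")
        if values.shape != self.spec.shape:
            raise RasterValidationError(
                f"values shape {values.shape} != grid shape {self.spec.shape}"
            )
        if self.kind in _FLOAT_KINDS:
            values = values.astype(np.float64, copy=False)
        else:
            if np.issubdtype(values.dtype, np.floating):
                finite = np.isfinite(values)
                if not np.array_equal(values[finite], np.round(values[finite])):
                    raise RasterValidationError(f"{self.kind} raster requires integer values")
                filled = np.where(finite, values, self.spec.nodata)
                values = filled.astype(np.int32)
            else:
                values = values.astype(np.int32, copy=False)
        self.values = values
        self.validate()

    # -- nodata handling ---------------------------------------------------
    @property
    def nodata_mask(self) -> np.ndarray:
        """Boolean array, True where the cell carries no data."""
        if self.kind == "travel_time":
            return np.isnan(self.values)
        if self.kind in _FLOAT_KINDS:
            return np.isnan(self.values)
        return self.values == int(self.spec.nodata)

    @property
    def valid_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        """Raise :class:`RasterValidationError` on any kind-invariant breach."""
        v = self.values
        if self.kind == "friction":
            bad = np.asarray(~np.isnan(v) & ~(v > 0)).nonzero()
            if bad[0].size:
                r, c = int(bad[0][0]), int(bad[1][0])
                raise RasterValidationError(
                    f"friction must be > 0 everywhere; cell ({r}, {c}) = {v[r, c]}"
                )
            inf = np.asarray(np.isinf(v)).nonzero()
            if inf[0].size:
                r, c = int(inf[0][0]), int(inf[1][0])
                raise RasterValidationError(f"friction must be finite; cell ({r}, {c}) is infinite")
        elif self.kind == "population":
            bad = np.asarray(~np.isnan(v) & ~((v >= 0) & np.isfinite(v))).nonzero()
            if bad[0].size:
                r, c = int(bad[0][0]), int(bad[1][0])
                raise RasterValidationError(
                    f"population must be finite and >= 0; cell ({r}, {c}) = {v[r, c]}"
                )
        elif self.kind == "travel_time":
            bad = np.asarray(~np.isnan(v) & (v < 0)).nonzero()
            if bad[0].size:
                r, c = int(bad[0][0]), int(bad[1][0])
                raise RasterValidationError(
                    f"travel time must be >= 0; cell ({r}, {c}) = {v[r, c]}"
                )
        elif self.kind == "mask":
            valid = v[self.valid_mask]
            if valid.size and not np.isin(valid, (0, 1)).all():
                raise RasterValidationError("mask values must be 0 or 1")
        else:  # zone, heatmap_class
            valid = v[self.valid_mask]
            if valid.size and (valid < 0).any():
                raise RasterValidationError(f"{self.kind} codes must be nonnegative")

    def copy(self) -> "Raster":
        return Raster(self.spec, self.values.copy(), self.kind)


def align_check(a: Raster, b: Raster) -> bool:
    """True iff ``a`` and ``b`` share the same grid (all spec fields but nodata)."""
    return a.spec.aligned_with(b.spec)


def require_aligned(*rasters: Raster) -> None:
    """Raise :class:`AlignmentError` unless all rasters share one grid."""
    first = rasters[0]
    for other in rasters[1:]:
        if not align_check(first, other):
            raise AlignmentError(
                f"rasters are not aligned: {first.kind} grid {first.spec} "
                f"vs {other.kind} grid {other.spec}"
            )


def _iter_pages(path: str) -> Iterator:
    with tifffile.TiffFile(path) as tf:
        yield from tf.pages


def read_raster(path: str | os.PathLike, kind: str) -> Raster:
    """Read a single-band GeoTIFF as a :class:`Raster` of the given kind.

    The geotransform is taken from the ModelPixelScale / ModelTiepoint tags,
    the nodata sentinel from the GDAL_NODATA tag.  Files with more than one
    band or with non-square cells are rejected.
    """
    path = os.fspath(path)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    with tifffile.TiffFile(path) as tf:
        if len(tf.pages) != 1:
            raise RasterValidationError(f"{path}: expected a single-page TIFF, got {len(tf.pages)} pages")
        page = tf.pages[0]
        if page.samplesperpixel != 1:
            raise RasterValidationError(
                f"{path}: expected a single-band raster, got {page.samplesperpixel} bands"
            )
        data = page.asarray()

        scale_tag = page.tags.get(_TAG_MODEL_PIXEL_SCALE)
        tiepoint_tag = page.tags.get(_TAG_MODEL_TIEPOINT)
        if scale_tag is None or tiepoint_tag is None:
            raise RasterValidationError(f"{path}: missing georeferencing tags")
        sx, sy = float(scale_tag.value[0]), float(scale_tag.value[1])
        if not math.isclose(sx, sy, rel_tol=1e-9):
            raise RasterValidationError(
                f"{path}: non-square cells ({sx} x {sy} m) are not supported"
            )
        tp = tiepoint_tag.value
        # tiepoint maps raster (i, j) to world (x, y); origin of the UL corner
        x_origin = float(tp[3]) - float(tp[0]) * sx
        y_origin = float(tp[4]) + float(tp[1]) * sy

        nodata_tag = page.tags.get(_TAG_GDAL_NODATA)
        nodata = float(nodata_tag.value) if nodata_tag is not None else -9999.0
        crs_tag = page.tags.get(_TAG_GEO_ASCII)
        crs_id = str(crs_tag.value).rstrip("|") if crs_tag is not None else "LOCAL"

    spec = GridSpec(
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        cell_size_m=sx,
        x_origin=x_origin,
        y_origin=y_origin,
        crs_id=crs_id,
        nodata=nodata,
    )
    if kind in _FLOAT_KINDS:
        values = data.astype(np.float64)
        at_sentinel = values == nodata
        values[at_sentinel] = np.inf if kind == "travel_time" else np.nan
    else:
        values = data.astype(np.int32)
    return Raster(spec, values, kind)


def write_raster(raster: Raster, path: str | os.PathLike) -> None:
    """Write a :class:`Raster` to disk as a single-band GeoTIFF.

    ``read_raster(write_raster(r))`` is the identity on values, nodata
    placement, and grid spec.  Float kinds are stored as float64 with nodata
    (NaN, and +inf for travel time) replaced by the sentinel; integer kinds as
    int32.
    """
    path = os.fspath(path)
    raster.validate()
    spec = raster.spec
    if raster.kind in _FLOAT_KINDS:
        out = raster.values.astype(np.float64, copy=True)
        out[~np.isfinite(out)] = spec.nodata
    else:
        out = raster.values.astype(np.int32, copy=True)
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size_m, spec.cell_size_m, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.x_origin, spec.y_origin, 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, repr(spec.nodata) if out.dtype.kind == "f" else str(int(spec.nodata))),
        (_TAG_GEO_ASCII, "s", 0, spec.crs_id + "|"),
    ]
    tifffile.imwrite(path, out, extratags=extratags)
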