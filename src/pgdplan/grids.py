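"""Planar grid data model and raster/table I/O.

All spatial layers in the pipeline live on a single shared analysis grid:
square cells, row 0 at the top-left origin, 0-based indices, half-open cell
extents ``[x0, x0 + cell) x (y0 - cell, y0]`` (left/top edges inclusive).
No resampling or reprojection is performed anywhere; inputs that do not
align raise :class:`AlignmentError` instead of being silently warped.

Rasters are read and written as single-band GeoTIFFs via :mod:`tifffile`,
using the standard GeoTIFF tags (ModelPixelScale, ModelTiepoint,
GDAL_NODATA and a citation GeoKey carrying the CRS identifier).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence, Union

import numpy as np
import pandas as pd
import tifffile

__all__ = [
    "GridSpec",
    "ValueGrid",
    "LabelGrid",
    "GridError",
    "AlignmentError",
    "RasterReadError",
    "MultiBandError",
    "MissingGeoreferenceError",
    "read_grid",
    "write_grid",
    "check_alignment",
    "points_to_cells",
    "read_points",
]

# GeoTIFF tag codes
_TAG_MODEL_PIXEL_SCALE = 33550
_TAG_MODEL_TIEPOINT = 33922
_TAG_GEO_KEY_DIRECTORY = 34735
_TAG_GEO_ASCII_PARAMS = 34737
_TAG_GDAL_NODATA = 42113

#: key id of the citation entry in the GeoTIFF key directory
_GT_CITATION_KEY = 1026


class GridError(Exception):
    """Base class for grid-related failures."""


class AlignmentError(GridError):
    """Two grids that must share a spec do not; names the offending field."""


class RasterReadError(GridError):
    """File missing or not a readable TIFF."""


class MultiBandError(RasterReadError):
    """Raster has more than one band/sample; only single-band is supported."""


class MissingGeoreferenceError(RasterReadError):
    """Raster lacks the GeoTIFF pixel-scale/tiepoint tags."""


@dataclass(frozen=True)
class GridSpec:
    """Geometry of the shared analysis grid.

    ``origin_x, origin_y`` are the map coordinates of the *top-left corner*
    of cell (0, 0); ``cell_size`` is the square cell edge in map units.
    """

    n_rows: int
    n_cols: int
    origin_x: float
    origin_y: float
    cell_size: float
    crs_id: str = "unknown"
    nodata: float = -9999.0

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise GridError("grid must have at least one row and column")
        if not self.cell_size > 0:
            raise GridError("cell_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def cell_area(self) -> float:
        return self.cell_size**2

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """(x, y) map coordinates of all cell centers, shaped like the grid."""
        cols = np.arange(self.n_cols)
        rows = np.arange(self.n_rows)
        x = self.origin_x + (cols + 0.5) * self.cell_size
        y = self.origin_y - (rows + 0.5) * self.cell_size
        return np.meshgrid(x, y)


@dataclass
class ValueGrid:
    """Real-valued raster on a :class:`GridSpec`; ``spec.nodata`` marks holes."""

    spec: GridSpec
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        if self.values.shape != self.spec.shape:
            raise GridError(
                f"values shape {self.values.shape} != spec shape {self.spec.shape}"
            )
        bad = ~np.isfinite(self.values) & ~self.nodata_mask
        if bad.any():
            raise GridError(f"{int(bad.sum())} non-finite values outside nodata")

    @property
    def nodata_mask(self) -> np.ndarray:
        with np.errstate(invalid="ignore"):
            return (self.values == self.spec.nodata) | ~np.isfinite(self.values)

    @property
    def data_mask(self) -> np.ndarray:
        return ~self.nodata_mask

    def filled(self, fill: float = np.nan) -> np.ndarray:
        out = self.values.copy()
        out[self.nodata_mask] = fill
        return out


@dataclass
class LabelGrid:
    """Integer-labeled raster; label 0 is reserved for nodata / outside mask."""

    spec: GridSpec
    labels: np.ndarray

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        if not np.issubdtype(self.labels.dtype, np.integer):
            if not np.array_equal(self.labels, np.round(self.labels)):
                raise GridError("labels must be integers")
            self.labels = self.labels.astype(np.int32)
        if self.labels.shape != self.spec.shape:
            raise GridError(
                f"labels shape {self.labels.shape} != spec shape {self.spec.shape}"
            )
        if (self.labels < 0).any():
            raise GridError("labels must be non-negative (0 = nodata)")

    @property
    def data_mask(self) -> np.ndarray:
        return self.labels > 0

    def label_set(self) -> np.ndarray:
        """Sorted distinct labels present, excluding the nodata label 0."""
        u = np.unique(self.labels)
        return u[u > 0]


Grid = Union[ValueGrid, LabelGrid]


def _grid_spec_of(grid: Grid) -> GridSpec:
    return grid.spec


def check_alignment(grids: Iterable[Grid | GridSpec]) -> None:
    """Verify every grid shares one spec; raise :class:`AlignmentError` if not.

    The error message names the first field that differs.  No resampling is
    ever attempted.
    """
    specs = [g if isinstance(g, GridSpec) else _grid_spec_of(g) for g in grids]
    if not specs:
        raise GridError("need at least one grid")
    ref = specs[0]
    for i, s in enumerate(specs[1:], start=1):
        for fld in ("n_rows", "n_cols", "origin_x", "origin_y", "cell_size", "crs_id", "nodata"):
            if getattr(s, fld) != getattr(ref, fld):
                raise AlignmentError(
                    f"grid {i} differs from grid 0 in {fld}: "
                    f"{getattr(s, fld)!r} != {getattr(ref, fld)!r}"
                )


# ---------------------------------------------------------------------------
# GeoTIFF I/O


def write_grid(grid: Grid, path: str | Path) -> None:
    """Write a single-band GeoTIFF with pixel scale, tiepoint and nodata tags."""
    spec = grid.spec
    if isinstance(grid, LabelGrid):
        data = grid.labels.astype(np.int32)
        nodata_repr = "0"
    else:
        data = grid.values.astype(np.float64)
        nodata_repr = repr(float(spec.nodata))
    ascii_params = spec.crs_id + "|"
    # GeoKeyDirectory: version 1.1.0, one key: GTCitation -> ascii params
    key_dir = np.array(
        [1, 1, 0, 1, _GT_CITATION_KEY, _TAG_GEO_ASCII_PARAMS, len(ascii_params), 0],
        dtype=np.uint16,
    )
    extratags = [
        (_TAG_MODEL_PIXEL_SCALE, "d", 3, (spec.cell_size, spec.cell_size, 0.0)),
        (_TAG_MODEL_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, spec.origin_x, spec.origin_y, 0.0)),
        (_TAG_GEO_KEY_DIRECTORY, "H", len(key_dir), tuple(int(v) for v in key_dir)),
        (_TAG_GEO_ASCII_PARAMS, "s", len(ascii_params), ascii_params),
        (_TAG_GDAL_NODATA, "s", len(nodata_repr), nodata_repr),
    ]
    tifffile.imwrite(path, data, extratags=extratags, photometric="minisblack")


def read_grid(path: str | Path, kind: str = "value") -> Grid:
    """Read a single-band GeoTIFF as a :class:`ValueGrid` or :class:`LabelGrid`.

    Parameters
    ----------
    path : path to the raster.
    kind : ``"value"`` for real-valued grids, ``"label"`` for integer labels.

    Raises
    ------
    RasterReadError : file missing or unreadable.
    MultiBandError : more than one band.
    MissingGeoreferenceError : pixel-scale / tiepoint tags absent.
    """
    if kind not in ("value", "label"):
        raise ValueError(f"kind must be 'value' or 'label', got {kind!r}")
    path = Path(path)
    if not path.exists():
        raise RasterReadError(f"no such file: {path}")
    try:
        with tifffile.TiffFile(path) as tif:
            if len(tif.pages) > 1:
                raise MultiBandError(f"{path}: {len(tif.pages)} pages, expected 1")
            page = tif.pages[0]
            if page.samplesperpixel != 1:
                raise MultiBandError(
                    f"{path}: {page.samplesperpixel} samples per pixel, expected 1"
                )
            data = page.asarray()
            tags = {t.code: t.value for t in page.tags.values()}
    except MultiBandError:
        raise
    except Exception as exc:  # noqa: BLE001 - normalize into RasterReadError
        raise RasterReadError(f"cannot read {path}: {exc}") from exc
    if data.ndim != 2:
        raise MultiBandError(f"{path}: data has {data.ndim} dimensions, expected 2")
    if _TAG_MODEL_PIXEL_SCALE not in tags or _TAG_MODEL_TIEPOINT not in tags:
        raise MissingGeoreferenceError(f"{path}: no GeoTIFF pixel scale/tiepoint tags")
    scale = tags[_TAG_MODEL_PIXEL_SCALE]
    tiepoint = tags[_TAG_MODEL_TIEPOINT]
    crs_id = "unknown"
    if _TAG_GEO_ASCII_PARAMS in tags:
        crs_id = str(tags[_TAG_GEO_ASCII_PARAMS]).rstrip("|\x00")
    nodata = -9999.0
    if _TAG_GDAL_NODATA in tags:
        nodata = float(str(tags[_TAG_GDAL_NODATA]).rstrip("\x00"))
    spec = GridSpec(
        n_rows=data.shape[0],
        n_cols=data.shape[1],
        origin_x=float(tiepoint[3]),
        origin_y=float(tiepoint[4]),
        cell_size=float(scale[0]),
        crs_id=crs_id,
        nodata=nodata,
    )
    if kind == "label":
        return LabelGrid(spec=spec, labels=data.astype(np.int64))
    return ValueGrid(spec=spec, values=data.astype(np.float64))


# ---------------------------------------------------------------------------
# Point tables


#: sentinel row/col for points falling outside the grid extent
OUTSIDE = -1


def points_to_cells(
    x: Sequence[float] | np.ndarray,
    y: Sequence[float] | np.ndarray,
    spec: GridSpec,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Map point coordinates to (row, col) cell indices.

    A point belongs to the cell whose half-open extent
    ``[x0, x0 + cell) x (y0 - cell, y0]`` contains it: left and top edges
    inclusive.  Points outside the grid get ``row = col = OUTSIDE`` and
    ``inside = False`` — they are flagged, never dropped.

    Returns ``(rows, cols, inside)``.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise GridError("non-finite point coordinates")
    col = np.floor((x - spec.origin_x) / spec.cell_size).astype(np.int64)
    # floor((y0 - y)/cell) puts the top edge of row r in row r, so the
    # (y0 - cell, y0] half-open vertical extent holds without a correction
    row = np.floor((spec.origin_y - y) / spec.cell_size).astype(np.int64)
    inside = (row >= 0) & (row < spec.n_rows) & (col >= 0) & (col < spec.n_cols)
    row = np.where(inside, row, OUTSIDE)
    col = np.where(inside, col, OUTSIDE)
    return row, col, inside


def read_points(path: str | Path) -> pd.DataFrame:
    """Read a point table CSV with required columns ``id, x, y`` (+ payload)."""
    df = pd.read_csv(path)
    missing = {"id", "x", "y"} - set(df.columns)
    if missing:
        raise GridError(f"point table missing columns: {sorted(missing)}")
    if not np.isfinite(df["x"]).all() or not np.isfinite(df["y"]).all():
        raise GridError("non-finite point coordinates in table")
    return df
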