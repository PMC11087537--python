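"""Grid-aligned raster containers shared across the pipeline.

All rasters live on an explicit :class:`GridSpec`: a north-up, square-pixel
grid whose cell (row 0, col 0) is the upper-left cell.  A point takes the
value of the cell containing it; cells are half-open ``[left, right)`` in x
and closed at the bottom edge in y, so every point in the grid's interior
belongs to exactly one cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

__all__ = [
    "GridSpec",
    "MapMetadata",
    "ClassRaster",
    "BinaryCropMap",
    "NDVICube",
]


@dataclass(frozen=True)
class GridSpec:
    """A north-up raster grid with square pixels.

    Parameters
    ----------
    origin_x, origin_y
        Map coordinates of the *upper-left corner* of the upper-left pixel.
    pixel_size
        Side length of each (square) pixel in map units; must be > 0.
    width, height
        Grid dimensions in pixels (columns, rows); each >= 1.
    crs
        Free-text coordinate reference system identifier. The pipeline never
        reprojects; all inputs for one analysis must share a CRS.
    """

    origin_x: float
    origin_y: float
    pixel_size: float
    width: int
    height: int
    crs: str = "local"

    def __post_init__(self) -> None:
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be > 0")
        if self.width < 1 or self.height < 1:
            raise ValueError("grid must contain at least one pixel")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.height, self.width)

    @property
    def n_pixels(self) -> int:
        return self.width * self.height

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(min_x, min_y, max_x, max_y) of the full grid extent."""
        return (
            self.origin_x,
            self.origin_y - self.height * self.pixel_size,
            self.origin_x + self.width * self.pixel_size,
            self.origin_y,
        )

    def cell_centers(self) -> tuple[np.ndarray, np.ndarray]:
        """Return (x, y) center-coordinate arrays of shape (height, width)."""
        s = self.pixel_size
        xs = self.origin_x + (np.arange(self.width) + 0.5) * s
        ys = self.origin_y - (np.arange(self.height) + 0.5) * s
        return np.meshgrid(xs, ys)

    def cell_index(self, x, y) -> tuple[np.ndarray, np.ndarray]:
        """Row/col of the cell containing each point (vectorised).

        Cells are half-open ``[left, right)`` in x; in y a point on a cell's
        bottom edge belongs to that cell, one on its top edge to the cell
        above.  Out-of-extent points get indices outside ``[0, h) x [0, w)``;
        use :meth:`contains` to screen them.
        """
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        col = np.floor((x - self.origin_x) / self.pixel_size).astype(np.int64)
        row = (np.ceil((self.origin_y - y) / self.pixel_size) - 1).astype(np.int64)
        return row, col

    def contains(self, row, col) -> np.ndarray:
        row = np.asarray(row)
        col = np.asarray(col)
        return (row >= 0) & (row < self.height) & (col >= 0) & (col < self.width)

    def same_geometry(self, other: "GridSpec") -> bool:
        return (
            math.isclose(self.origin_x, other.origin_x)
            and math.isclose(self.origin_y, other.origin_y)
            and math.isclose(self.pixel_size, other.pixel_size)
            and self.width == other.width
            and self.height == other.height
        )


@dataclass(frozen=True)
class MapMetadata:
    """Provenance of one candidate map: name, native resolution, nominal year."""

    name: str
    native_resolution: float
    nominal_year: int

    def __post_init__(self) -> None:
        if self.native_resolution <= 0:
            raise ValueError("native_resolution must be > 0")


def _validate_raster(grid: GridSpec, values: np.ndarray, nodata: np.ndarray) -> None:
    if values.shape != grid.shape:
        raise ValueError(f"values shape {values.shape} != grid shape {grid.shape}")
    if nodata.shape != grid.shape:
        raise ValueError("nodata mask shape mismatch")
    if nodata.dtype != bool:
        raise ValueError("nodata mask must be boolean")


@dataclass
class ClassRaster:
    """A raster of integer class codes or continuous values (fractions,
    probabilities) with a nodata mask.

    ``kind`` records the value domain — ``"codes"`` for categorical integer
    rasters, ``"continuous"`` for real-valued ones — so binarisation rules
    can reject a domain mismatch instead of silently misreading codes as
    fractions.
    """

    grid: GridSpec
    values: np.ndarray
    nodata: np.ndarray
    kind: str = "codes"  # "codes" | "continuous"

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        _validate_raster(self.grid, self.values, self.nodata)
        if self.kind not in ("codes", "continuous"):
            raise ValueError(f"unknown raster kind {self.kind!r}")
        if self.kind == "codes" and not np.issubdtype(self.values.dtype, np.integer):
            raise ValueError("code rasters must have integer dtype")


@dataclass
class BinaryCropMap:
    """A georeferenced crop (1) / non-crop (0) raster — the common currency
    of the pipeline."""

    grid: GridSpec
    values: np.ndarray
    nodata: np.ndarray
    metadata: MapMetadata | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.uint8)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        _validate_raster(self.grid, self.values, self.nodata)
        valid = self.values[~self.nodata]
        if valid.size and not np.isin(valid, (0, 1)).all():
            raise ValueError("binary map may contain only {0, 1, nodata}")

    @property
    def valid(self) -> np.ndarray:
        return ~self.nodata

    def crop_fraction(self) -> float:
        """Realised crop fraction over non-nodata pixels."""
        v = self.values[self.valid]
        if v.size == 0:
            raise ValueError("map has no valid pixels")
        return float(v.mean())

    def with_metadata(self, metadata: MapMetadata) -> "BinaryCropMap":
        return BinaryCropMap(self.grid, self.values, self.nodata, metadata)


@dataclass
class NDVICube:
    """A time series of NDVI rasters on one grid.

    ``values`` has shape (T, height, width) with NDVI in [-1, 1];
    ``dates`` are ISO date strings, one per timestep.
    """

    grid: GridSpec
    dates: Sequence[str]
    values: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[1:] != self.grid.shape:
            raise ValueError("cube must have shape (T, height, width) on its grid")
        if len(self.dates) != self.values.shape[0]:
            raise ValueError("one date per timestep required")
        if np.nanmin(self.values) < -1 - 1e-9 or np.nanmax(self.values) > 1 + 1e-9:
            raise ValueError("NDVI values must lie in [-1, 1]")

    @property
    def n_timesteps(self) -> int:
        return self.values.shape[0]
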