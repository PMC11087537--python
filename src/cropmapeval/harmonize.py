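"""Harmonisation of heterogeneous land-cover products onto a common binary
crop/non-crop grid: binarisation rules, temporal mode composites,
nearest-neighbour resampling, clipping to a region boundary, and mapped-area
counting.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import shapely

from .accuracy import MappedAreaSummary
from .rasters import BinaryCropMap, ClassRaster, GridSpec

logger = logging.getLogger(__name__)

__all__ = [
    "CropClassRule",
    "binarize",
    "mode_composite",
    "resample_to_grid",
    "clip_to_boundary",
    "mapped_area",
]


@dataclass(frozen=True)
class CropClassRule:
    """One way of reading 'crop' off a product's native values.

    Exactly one variant is active:

    - ``code_set``: crop iff the pixel's class code is in a given set
      (generic land-cover products with named cropland classes).
    - ``threshold``: crop iff value > cutoff (strict) or >= cutoff
      (probability / score layers).
    - ``fraction_range``: crop iff a crop-area-fraction value lies in
      [low, high] (inclusive) — the convention of fractional crop masks.
    - ``mode_then_code``: take the per-pixel temporal mode of a stack of
      class rasters, then crop iff the mode equals one crop code (annual
      composites of per-date classifications).
    """

    variant: str
    codes: frozenset[int] | None = None
    cutoff: float | None = None
    strict: bool = True
    low: float | None = None
    high: float | None = None
    crop_code: int | None = None

    _VARIANTS = ("code_set", "threshold", "fraction_range", "mode_then_code")

    def __post_init__(self) -> None:
        if self.variant not in self._VARIANTS:
            raise ValueError(f"unknown rule variant {self.variant!r}")
        if self.variant == "fraction_range" and not (self.low < self.high):
            raise ValueError("fraction range requires low < high")

    @classmethod
    def code_set(cls, codes) -> "CropClassRule":
        return cls("code_set", codes=frozenset(int(c) for c in codes))

    @classmethod
    def threshold(cls, cutoff: float, strict: bool = True) -> "CropClassRule":
        return cls("threshold", cutoff=float(cutoff), strict=strict)

    @classmethod
    def fraction_range(cls, low: float, high: float) -> "CropClassRule":
        return cls("fraction_range", low=float(low), high=float(high))

    @classmethod
    def mode_then_code(cls, crop_code: int) -> "CropClassRule":
        return cls("mode_then_code", crop_code=int(crop_code))


def binarize(raster: ClassRaster | Sequence[ClassRaster], rule: CropClassRule) -> BinaryCropMap:
    """Apply a crop-class rule to a native product raster.

    ``mode_then_code`` rules accept a temporal stack (sequence of rasters on
    one grid); all other rules take a single raster whose value domain
    matches the rule (codes vs continuous), otherwise an error is raised.
    """
    if rule.variant == "mode_then_code":
        stack = list(raster) if not isinstance(raster, ClassRaster) else [raster]
        composited = mode_composite(stack)
        return binarize(composited, CropClassRule.code_set([rule.crop_code]))

    if not isinstance(raster, ClassRaster):
        raise TypeError("non-composite rules take a single ClassRaster")

    if rule.variant == "code_set":
        if raster.kind != "codes":
            raise ValueError("code-set rule requires a categorical (codes) raster")
        out = np.isin(raster.values, sorted(rule.codes))
    elif rule.variant == "threshold":
        if raster.kind != "continuous":
            raise ValueError("threshold rule requires a continuous raster")
        out = (raster.values > rule.cutoff) if rule.strict else (raster.values >= rule.cutoff)
    else:  # fraction_range
        if raster.kind != "continuous":
            raise ValueError("fraction-range rule requires a continuous raster")
        out = (raster.values >= rule.low) & (raster.values <= rule.high)

    return BinaryCropMap(raster.grid, out.astype(np.uint8), raster.nodata.copy())


def mode_composite(stack: Sequence[ClassRaster]) -> ClassRaster:
    """Per-pixel most frequent class across a temporal stack, ignoring
    nodata; ties resolve to the lowest class code.  A pixel nodata in every
    timestep stays nodata."""
    if len(stack) == 0:
        raise ValueError("mode composite of an empty stack")
    grid = stack[0].grid
    for r in stack:
        if not r.grid.same_geometry(grid):
            raise ValueError("all rasters in the stack must share one grid")
        if r.kind != "codes":
            raise ValueError("mode composite requires categorical rasters")

    values = np.stack([r.values for r in stack])
    nodata = np.stack([r.nodata for r in stack])
    codes = np.unique(values[~nodata]) if (~nodata).any() else np.array([0])

    # counts[c] = per-pixel frequency of codes[c]; argmax picks the first
    # (lowest) code on ties because codes is sorted ascending.
    counts = np.stack([((values == c) & ~nodata).sum(axis=0) for c in codes])
    mode = codes[np.argmax(counts, axis=0)]
    all_nodata = nodata.all(axis=0)
    return ClassRaster(grid, mode.astype(values.dtype), all_nodata, kind="codes")


def resample_to_grid(cropmap: BinaryCropMap, target: GridSpec) -> BinaryCropMap:
    """Nearest-neighbour resampling: each target cell takes the value of the
    source cell containing its center; target cells whose center falls off
    the source extent become nodata."""
    sb = cropmap.grid.bounds
    tb = target.bounds
    if sb[2] <= tb[0] or tb[2] <= sb[0] or sb[3] <= tb[1] or tb[3] <= sb[1]:
        raise ValueError("target grid does not overlap the map extent")

    cx, cy = target.cell_centers()
    row, col = cropmap.grid.cell_index(cx, cy)
    inside = cropmap.grid.contains(row, col)

    values = np.zeros(target.shape, dtype=np.uint8)
    nodata = np.ones(target.shape, dtype=bool)
    r_in, c_in = row[inside], col[inside]
    values[inside] = cropmap.values[r_in, c_in]
    nodata[inside] = cropmap.nodata[r_in, c_in]
    return BinaryCropMap(target, values, nodata, cropmap.metadata)


def clip_to_boundary(cropmap: BinaryCropMap, boundary) -> BinaryCropMap:
    """Set pixels whose centers fall outside the boundary polygon to nodata.

    Centers exactly on the polygon edge count as inside.  A boundary
    disjoint from the raster yields an all-nodata map with a warning.
    """
    boundary = shapely.geometry.shape(boundary) if isinstance(boundary, dict) else boundary
    if boundary.is_empty or not boundary.is_valid:
        raise ValueError("boundary must be a valid, non-empty polygon")

    cx, cy = cropmap.grid.cell_centers()
    inside = shapely.intersects_xy(boundary, cx.ravel(), cy.ravel()).reshape(cropmap.grid.shape)
    if not inside.any():
        warnings.warn("boundary contains no pixel centers; result is all nodata")
    nodata = cropmap.nodata | ~inside
    return BinaryCropMap(cropmap.grid, cropmap.values.copy(), nodata, cropmap.metadata)


def mapped_area(cropmap: BinaryCropMap) -> MappedAreaSummary:
    """Count mapped pixels per class (nodata excluded)."""
    v = cropmap.values[cropmap.valid]
    if v.size == 0:
        raise ValueError("map is entirely nodata")
    n_pos = int((v == 1).sum())
    return MappedAreaSummary(n_neg=int(v.size - n_pos), n_pos=n_pos)
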