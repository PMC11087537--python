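"""Probability sampling designs and the response-design quality filter.

Reference data for map evaluation come from a probability sample of point
locations — simple uniform random sampling within a region boundary, or
stratified random sampling with strata defined as intervals over a covariate
raster (e.g. mean annual NDVI) with equal allocation per stratum.  Each
point is labeled independently by two or more interpreters; only points with
unanimous labels are retained for analysis (the unanimity filter), which
keeps label noise in the final dataset low at the cost of discarding
ambiguous points.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import shapely
from shapely.geometry import shape as _geojson_shape

from .rasters import ClassRaster

logger = logging.getLogger(__name__)

__all__ = [
    "ReferencePoint",
    "ReferenceDataset",
    "SampleDesign",
    "Stratum",
    "sample_uniform",
    "sample_stratified",
    "consensus_filter",
    "summarize_dataset",
]


@dataclass(frozen=True)
class ReferencePoint:
    """One interpreter-labeled sample point.

    ``final_label`` is defined iff all interpreter labels agree (set by
    :func:`consensus_filter`); ``truth`` carries the simulated ground truth
    when the point comes from the synthetic generator.
    """

    id: str
    lon: float
    lat: float
    interpreter_labels: tuple[int, ...]
    final_label: int | None = None
    validity_start: str | None = None
    validity_end: str | None = None
    stratum: int | None = None
    truth: int | None = None

    def __post_init__(self) -> None:
        if len(self.interpreter_labels) < 2:
            raise ValueError("every point needs at least two interpreter labels")
        if any(l not in (0, 1) for l in self.interpreter_labels):
            raise ValueError("labels must be binary")
        unanimous = len(set(self.interpreter_labels)) == 1
        if self.final_label is not None and not unanimous:
            raise ValueError("final_label may only be set for unanimous points")


@dataclass(frozen=True)
class Stratum:
    """A left-open, right-closed interval (low, high] over a covariate."""

    low: float
    high: float

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise ValueError("stratum interval requires low < high")

    def contains(self, value) -> np.ndarray:
        value = np.asarray(value, dtype=float)
        return (value > self.low) & (value <= self.high)


@dataclass(frozen=True)
class SampleDesign:
    variant: str  # "uniform" | "stratified"
    strata: tuple[Stratum, ...] = ()
    n_per_stratum: int = 0

    def __post_init__(self) -> None:
        if self.variant not in ("uniform", "stratified"):
            raise ValueError(f"unknown design {self.variant!r}")
        if self.variant == "stratified":
            ivals = sorted(self.strata, key=lambda s: s.low)
            for a, b in zip(ivals, ivals[1:]):
                if b.low < a.high:
                    raise ValueError("strata intervals must be disjoint")


@dataclass(frozen=True)
class ReferenceDataset:
    region: str
    year: int
    points: tuple[ReferencePoint, ...]
    design: SampleDesign = SampleDesign("uniform")

    def __post_init__(self) -> None:
        for p in self.points:
            if p.final_label is None:
                raise ValueError("every retained point must carry a final label")

    @property
    def n_crop(self) -> int:
        return sum(1 for p in self.points if p.final_label == 1)

    @property
    def n_non_crop(self) -> int:
        return len(self.points) - self.n_crop


def _as_polygon(boundary):
    return _geojson_shape(boundary) if isinstance(boundary, dict) else boundary


def sample_uniform(boundary, n: int, seed: int) -> list[tuple[float, float]]:
    """Draw ``n`` points uniformly over a polygon's area by rejection
    sampling from its bounding box.  Points on the polygon edge count as
    inside.  Deterministic for a given seed."""
    boundary = _as_polygon(boundary)
    if n < 1:
        raise ValueError("n must be >= 1")
    if boundary.is_empty or boundary.area == 0:
        raise ValueError("boundary has zero area")
    minx, miny, maxx, maxy = boundary.bounds
    rng = np.random.default_rng(seed)
    out_x: list[float] = []
    out_y: list[float] = []
    # accept rate = area / bbox area; batch to amortise the polygon test
    batch = max(128, int(2 * n * (maxx - minx) * (maxy - miny) / boundary.area))
    while len(out_x) < n:
        xs = rng.uniform(minx, maxx, size=batch)
        ys = rng.uniform(miny, maxy, size=batch)
        keep = shapely.intersects_xy(boundary, xs, ys)
        out_x.extend(xs[keep])
        out_y.extend(ys[keep])
    return list(zip(out_x[:n], out_y[:n]))


def sample_stratified(
    covariate: ClassRaster,
    boundary,
    strata: Sequence[Stratum],
    n_per_stratum: int,
    seed: int,
    max_attempts: int = 1000,
) -> list[tuple[tuple[float, float], int]]:
    """Equal-allocation stratified random sample.

    Strata are (low, high] intervals over the covariate raster; each
    non-empty stratum receives exactly ``n_per_stratum`` points, placed
    uniformly over the stratum's footprint inside the boundary (rejection
    sampling).  A stratum with no eligible pixels gets zero points with a
    warning.  Returns (location, stratum index) pairs.
    """
    boundary = _as_polygon(boundary)
    design = SampleDesign("stratified", tuple(strata), n_per_stratum)  # validates disjoint
    rng = np.random.default_rng(seed)

    # Pre-screen stratum emptiness on pixel centers inside the boundary.
    cx, cy = covariate.grid.cell_centers()
    inside = shapely.intersects_xy(boundary, cx.ravel(), cy.ravel()).reshape(covariate.grid.shape)
    eligible = inside & ~covariate.nodata
    vals = covariate.values

    out: list[tuple[tuple[float, float], int]] = []
    for k, stratum in enumerate(design.strata):
        member = eligible & stratum.contains(vals)
        if not member.any():
            warnings.warn(f"stratum {k} ({stratum.low}, {stratum.high}] has no eligible pixels")
            continue
        got = 0
        for _ in range(max_attempts):
            need = n_per_stratum - got
            xs_ys = sample_uniform(boundary, max(need * 4, 64), int(rng.integers(2 ** 31)))
            xs = np.array([p[0] for p in xs_ys])
            ys = np.array([p[1] for p in xs_ys])
            row, col = covariate.grid.cell_index(xs, ys)
            ok = covariate.grid.contains(row, col)
            ok[ok] &= member[row[ok], col[ok]]
            for x, y in zip(xs[ok], ys[ok]):
                if got == n_per_stratum:
                    break
                out.append(((float(x), float(y)), k))
                got += 1
            if got == n_per_stratum:
                break
        else:
            raise RuntimeError(f"could not fill stratum {k} after {max_attempts} attempts")
    return out


def consensus_filter(
    points: Sequence[ReferencePoint],
    region: str = "",
    year: int = 0,
    design: SampleDesign | None = None,
) -> ReferenceDataset:
    """Retain exactly the points whose interpreter labels are unanimous,
    setting ``final_label`` to the common label; discard the rest."""
    if not points:
        warnings.warn("consensus_filter received no points; dataset is empty")
    retained = []
    for p in points:
        labels = set(p.interpreter_labels)
        if len(labels) == 1:
            retained.append(replace(p, final_label=labels.pop()))
    n_discarded = len(points) - len(retained)
    if n_discarded:
        logger.info("consensus_filter: discarded %d non-unanimous point(s) of %d",
                    n_discarded, len(points))
    return ReferenceDataset(
        region=region, year=year, points=tuple(retained),
        design=design or SampleDesign("uniform"),
    )


def summarize_dataset(dataset: ReferenceDataset) -> dict:
    """Summary-table row: total, crop and non-crop counts, and crop
    percentage (100·crop/total, one decimal)."""
    total = len(dataset.points)
    if total == 0:
        raise ValueError("cannot summarise an empty dataset")
    crop = dataset.n_crop
    return {
        "region": dataset.region,
        "year": dataset.year,
        "total": total,
        "crop": crop,
        "non_crop": total - crop,
        "crop_pct": round(100.0 * crop / total, 1),
    }
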