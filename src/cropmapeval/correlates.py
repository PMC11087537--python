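"""Cross-map synthesis: per-region means across maps, correlations of
accuracy with map resolution and temporal mismatch, and mask-based zonal
NDVI time series."""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import shapely
from scipy import stats

from .accuracy import MapEvaluation
from .rasters import BinaryCropMap, MapMetadata, NDVICube

__all__ = [
    "CorrelationResult",
    "NDVISeries",
    "country_mean_metrics",
    "temporal_mismatch",
    "metric_covariate_correlation",
    "masked_ndvi_series",
]

_COVARIATES = ("resolution", "temporal_mismatch")


@dataclass(frozen=True)
class CorrelationResult:
    """Pearson correlation of one mean metric against one map covariate.

    ``r`` is NaN when either vector has zero variance (undefined, flagged
    rather than silently zero).
    """

    metric: str
    covariate: str
    r: float
    excluded: tuple[str, ...] = ()
    n_maps: int = 0

    @property
    def defined(self) -> bool:
        return not math.isnan(self.r)


@dataclass(frozen=True)
class NDVISeries:
    """Zonal mean NDVI per timestep; NaN where the mask selects no pixel."""

    dates: tuple[str, ...]
    values: tuple[float, ...]
    mask_name: str = ""
    region: str = ""


def country_mean_metrics(evals: Sequence[MapEvaluation]) -> dict[str, tuple[float, float]]:
    """Mean and sample SD (divisor n-1) of each metric's value across maps,
    the 'mean ± SD across all maps' column of a per-region results table."""
    if len(evals) < 2:
        raise ValueError("need at least two evaluations to average")
    out: dict[str, tuple[float, float]] = {}
    for metric in ("accuracy", "precision", "recall", "f1"):
        vals = np.array([e.metrics()[metric].value for e in evals])
        out[metric] = (float(vals.mean()), float(vals.std(ddof=1)))
    return out


def temporal_mismatch(map_year: int, reference_year: int) -> int:
    """Absolute difference in years between a map's nominal year and the
    reference data year."""
    return abs(int(map_year) - int(reference_year))


def metric_covariate_correlation(
    mean_metrics: Mapping[str, Mapping[str, float]],
    metadata: Sequence[MapMetadata],
    covariate: str,
    reference_year: int | None = None,
    exclusions: Sequence[str] = (),
) -> list[CorrelationResult]:
    """Pearson r between each metric's per-map mean and a map covariate.

    Parameters
    ----------
    mean_metrics
        ``{map name: {metric name: mean value across regions}}``.
    metadata
        Per-map name / native resolution / nominal year.
    covariate
        ``"resolution"`` (native m/px) or ``"temporal_mismatch"`` (absolute
        years between nominal and reference year; requires
        ``reference_year``).
    exclusions
        Map names removed before computing r (e.g. coarse-resolution
        outliers); at least three maps must remain.
    """
    if covariate not in _COVARIATES:
        raise ValueError(f"covariate must be one of {_COVARIATES}")
    meta = {m.name: m for m in metadata if m.name not in set(exclusions)}
    kept = [name for name in mean_metrics if name in meta]
    if len(kept) < 3:
        raise ValueError("need at least three maps after exclusions")

    if covariate == "resolution":
        x = np.array([meta[n].native_resolution for n in kept], dtype=float)
    else:
        if reference_year is None:
            raise ValueError("temporal_mismatch requires a reference_year")
        x = np.array([temporal_mismatch(meta[n].nominal_year, reference_year) for n in kept],
                     dtype=float)

    results = []
    metrics = sorted({m for d in mean_metrics.values() for m in d})
    for metric in metrics:
        y = np.array([mean_metrics[n][metric] for n in kept], dtype=float)
        if np.ptp(x) == 0 or np.ptp(y) == 0:
            warnings.warn(f"zero variance: correlation of {metric} vs {covariate} undefined")
            r = float("nan")
        else:
            r = float(stats.pearsonr(x, y).statistic)
        results.append(CorrelationResult(metric, covariate, r,
                                         excluded=tuple(exclusions), n_maps=len(kept)))
    return results


def masked_ndvi_series(cube: NDVICube, mask: BinaryCropMap, region=None,
                       mask_name: str | None = None, region_name: str = "") -> NDVISeries:
    """Per-timestep mean NDVI over pixels where the mask is crop (and the
    pixel center falls in the region polygon, if one is given).

    The mask must already live on the cube's grid — resample coarse NDVI
    grids first.  An empty selection yields NaNs with a warning.
    """
    if not mask.grid.same_geometry(cube.grid):
        raise ValueError("mask must be on the NDVI cube's grid; resample it first")
    select = (mask.values == 1) & mask.valid
    if region is not None:
        from shapely.geometry import shape as _shape
        poly = _shape(region) if isinstance(region, dict) else region
        cx, cy = cube.grid.cell_centers()
        select &= shapely.intersects_xy(poly, cx.ravel(), cy.ravel()).reshape(cube.grid.shape)

    if not select.any():
        warnings.warn("mask selects no pixels in the region; series is undefined")
        vals = tuple(float("nan") for _ in cube.dates)
    else:
        vals = tuple(float(v) for v in cube.values[:, select].mean(axis=1))
    name = mask_name or (mask.metadata.name if mask.metadata else "mask")
    return NDVISeries(tuple(cube.dates), vals, mask_name=name, region=region_name)
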