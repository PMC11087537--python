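"""Synthetic study generator: truth landscapes, degraded product maps,
interpreter labels and NDVI cubes with known parameters.

Every generator is a pure function of its inputs and a seed, so the
pipeline's estimators can be checked against closed forms: a product made by
flipping crop pixels with probability *o* (omission) and non-crop pixels
with probability *c* (commission) over a landscape with crop fraction *f*
has, by construction,

    producer's accuracy  PA = 1 - o
    user's accuracy      UA = (1-o) f / ((1-o) f + c (1-f))

and interpreter labels that are independently wrong with probability ε give
a unanimity-filter retention rate of (1-ε)^L + ε^L for L interpreters.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .rasters import BinaryCropMap, GridSpec, MapMetadata, NDVICube

__all__ = [
    "NDVIParams",
    "ProductSpec",
    "SyntheticScenario",
    "generate_true_landscape",
    "degrade_map",
    "generate_interpreter_labels",
    "generate_ndvi_cube",
    "expected_users_accuracy",
]


@dataclass(frozen=True)
class NDVIParams:
    """Seasonal sinusoid parameters for crop and non-crop pixels.

    Crop pixels green up and senesce within the season, so they get a larger
    seasonal amplitude than the non-crop background; both share the timing
    of the peak.  NDVI(t) = baseline + amplitude * sin(2π t / T), clipped to
    [-1, 1], plus Gaussian noise with the given sd.
    """

    crop_baseline: float = 0.25
    crop_amplitude: float = 0.35
    noncrop_baseline: float = 0.30
    noncrop_amplitude: float = 0.10
    noise_sd: float = 0.05
    n_timesteps: int = 23  # one year of 16-day composites

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_timesteps < 1:
            raise ValueError("need at least one timestep")


@dataclass(frozen=True)
class ProductSpec:
    """Error model and metadata for one degraded candidate map."""

    name: str
    native_resolution: float
    nominal_year: int
    omission_rate: float
    commission_rate: float

    def __post_init__(self) -> None:
        if self.native_resolution <= 0:
            raise ValueError("native_resolution must be > 0")
        for r in (self.omission_rate, self.commission_rate):
            if not 0.0 <= r <= 1.0:
                raise ValueError("error rates must lie in [0, 1]")

    def metadata(self) -> MapMetadata:
        return MapMetadata(self.name, self.native_resolution, self.nominal_year)


def _default_products() -> tuple[ProductSpec, ...]:
    # Emulates the study's spread: native resolutions from 10 m to 1000 m
    # (integer multiples of the 10 m common grid), nominal years 2009-2020,
    # and error rates spanning good to poor products.
    return (
        ProductSpec("prod-10m-2019", 10, 2019, omission_rate=0.10, commission_rate=0.03),
        ProductSpec("prod-10m-2020", 10, 2020, omission_rate=0.15, commission_rate=0.05),
        ProductSpec("prod-20m-2016", 20, 2016, omission_rate=0.25, commission_rate=0.08),
        ProductSpec("prod-30m-2019", 30, 2019, omission_rate=0.20, commission_rate=0.05),
        ProductSpec("prod-100m-2019", 100, 2019, omission_rate=0.30, commission_rate=0.10),
        ProductSpec("prod-300m-2009", 300, 2009, omission_rate=0.45, commission_rate=0.20),
        ProductSpec("prod-1000m-2017", 1000, 2017, omission_rate=0.50, commission_rate=0.25),
    )


@dataclass(frozen=True)
class SyntheticScenario:
    """Everything needed to simulate one region's worth of study inputs."""

    seed: int = 0
    grid: GridSpec = field(default_factory=lambda: GridSpec(0.0, 3000.0, 10.0, 300, 300))
    crop_fraction: float = 0.3
    products: tuple[ProductSpec, ...] = field(default_factory=_default_products)
    n_reference_points: int = 500
    interpreters_per_point: int = 2
    label_noise_rate: float = 0.05
    ndvi_params: NDVIParams = field(default_factory=NDVIParams)
    smoothing_sigma: float = 3.0  # patch scale of the landscape, in pixels
    region: str = "synthetic"
    reference_year: int = 2019

    def __post_init__(self) -> None:
        if not 0.0 < self.crop_fraction < 1.0:
            raise ValueError("crop_fraction must lie strictly inside (0, 1)")
        if not 0.0 <= self.label_noise_rate < 0.5:
            raise ValueError("label_noise_rate must lie in [0, 0.5)")
        if self.interpreters_per_point < 2:
            raise ValueError("at least two interpreters per point")
        if self.n_reference_points < 1:
            raise ValueError("need at least one reference point")


def generate_true_landscape(scenario: SyntheticScenario) -> BinaryCropMap:
    """Spatially autocorrelated binary truth landscape.

    White Gaussian noise is smoothed with a Gaussian kernel
    (``scenario.smoothing_sigma`` pixels) and thresholded at the empirical
    quantile that yields the target crop fraction, producing field-like
    patches whose realised crop fraction matches ``crop_fraction`` to within
    one pixel's worth of area.
    """
    grid = scenario.grid
    if grid.n_pixels == 0:
        raise ValueError("degenerate grid")
    rng = np.random.default_rng(scenario.seed)
    noise = rng.standard_normal(grid.shape)
    smooth = ndimage.gaussian_filter(noise, sigma=scenario.smoothing_sigma)
    cut = np.quantile(smooth, 1.0 - scenario.crop_fraction)
    values = (smooth > cut).astype(np.uint8)
    nodata = np.zeros(grid.shape, dtype=bool)
    meta = MapMetadata("truth", grid.pixel_size, scenario.reference_year)
    return BinaryCropMap(grid, values, nodata, meta)


def _aggregate_majority(truth: BinaryCropMap, factor: int) -> BinaryCropMap:
    """Block-aggregate a fine map to a factor-times-coarser grid by majority
    of covered pixels; exact ties go to non-crop (the dominant-class
    semantics of coarse land-cover products)."""
    g = truth.grid
    out_h = -(-g.height // factor)
    out_w = -(-g.width // factor)
    pad_h = out_h * factor - g.height
    pad_w = out_w * factor - g.width
    vals = np.pad(truth.values.astype(np.int64), ((0, pad_h), (0, pad_w)))
    valid = np.pad(truth.valid.astype(np.int64), ((0, pad_h), (0, pad_w)))
    crop = vals * valid
    block = lambda a: a.reshape(out_h, factor, out_w, factor).sum(axis=(1, 3))
    n_crop, n_valid = block(crop), block(valid)
    values = (2 * n_crop > n_valid).astype(np.uint8)  # strict majority
    nodata = n_valid == 0
    coarse_grid = GridSpec(g.origin_x, g.origin_y, g.pixel_size * factor,
                           out_w, out_h, g.crs)
    return BinaryCropMap(coarse_grid, values, nodata, truth.metadata)


def degrade_map(truth: BinaryCropMap, spec: ProductSpec, seed: int) -> BinaryCropMap:
    """Produce one candidate map from the truth under the flip error model.

    If the product's native resolution is coarser than the truth grid (by an
    integer factor), the truth is first aggregated to native resolution by
    block majority; then each crop pixel is flipped to non-crop with
    probability ``omission_rate`` and each non-crop pixel to crop with
    probability ``commission_rate``, independently.
    """
    ratio = spec.native_resolution / truth.grid.pixel_size
    if ratio >= 1:
        factor = round(ratio)
        if abs(factor - ratio) > 1e-9:
            raise ValueError("native_resolution must be an integer multiple of the truth grid")
        base = _aggregate_majority(truth, factor) if factor > 1 else truth
    else:
        inv = round(1 / ratio)
        if abs(inv - 1 / ratio) > 1e-9:
            raise ValueError("truth grid must be an integer multiple of native_resolution")
        g = truth.grid
        fine = GridSpec(g.origin_x, g.origin_y, g.pixel_size / inv,
                        g.width * inv, g.height * inv, g.crs)
        base = BinaryCropMap(fine, np.repeat(np.repeat(truth.values, inv, 0), inv, 1),
                             np.repeat(np.repeat(truth.nodata, inv, 0), inv, 1),
                             truth.metadata)

    rng = np.random.default_rng(seed)
    u = rng.random(base.grid.shape)
    is_crop = base.values == 1
    flipped = np.where(is_crop, u < spec.omission_rate, u < spec.commission_rate)
    values = np.where(flipped, 1 - base.values, base.values).astype(np.uint8)
    values[base.nodata] = 0
    return BinaryCropMap(base.grid, values, base.nodata.copy(), spec.metadata())


def generate_interpreter_labels(truth_label: int, n_interpreters: int,
                                noise_rate: float, seed: int) -> tuple[int, ...]:
    """Independent interpreter labels: each equals the truth with
    probability 1 - noise_rate.  noise_rate >= 0.5 is rejected (labels would
    carry no information)."""
    if n_interpreters < 2:
        raise ValueError("at least two interpreters required")
    if not 0.0 <= noise_rate < 0.5:
        raise ValueError("noise_rate must lie in [0, 0.5)")
    if truth_label not in (0, 1):
        raise ValueError("truth_label must be 0 or 1")
    rng = np.random.default_rng(seed)
    wrong = rng.random(n_interpreters) < noise_rate
    return tuple(int(truth_label ^ w) for w in wrong)


def expected_users_accuracy(omission: float, commission: float, crop_fraction: float) -> float:
    """Closed-form UA of a flip-model product: (1-o)f / ((1-o)f + c(1-f))."""
    num = (1 - omission) * crop_fraction
    den = num + commission * (1 - crop_fraction)
    return num / den if den > 0 else 0.0


def generate_ndvi_cube(scenario: SyntheticScenario, truth: BinaryCropMap | None = None) -> NDVICube:
    """NDVI time series over the scenario grid.

    Crop and non-crop pixels follow sinusoidal seasonal curves (crop with
    the larger amplitude) plus i.i.d. Gaussian noise; values are clipped to
    the NDVI range [-1, 1].  Dates are evenly spaced over the reference
    year.
    """
    if truth is None:
        truth = generate_true_landscape(scenario)
    p = scenario.ndvi_params
    T = p.n_timesteps
    rng = np.random.default_rng(scenario.seed + 1)

    t = np.arange(T)
    phase = np.sin(2 * np.pi * t / T)  # peak at t = T/4
    is_crop = truth.values == 1
    baseline = np.where(is_crop, p.crop_baseline, p.noncrop_baseline)
    amplitude = np.where(is_crop, p.crop_amplitude, p.noncrop_amplitude)

    series = baseline[None] + amplitude[None] * phase[:, None, None]
    if p.noise_sd > 0:
        series = series + rng.normal(0.0, p.noise_sd, size=series.shape)
    series = np.clip(series, -1.0, 1.0)

    year = scenario.reference_year
    day_of_year = np.linspace(1, 353, T).round().astype(int)
    base = np.datetime64(f"{year}-01-01") - 1
    dates = [str(base + d) for d in day_of_year]
    return NDVICube(truth.grid, dates, series)
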