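"""End-to-end orchestration: from a run configuration to the full artifact
bundle (evaluation table, consensus summary, agreement and rank matrices,
consensus and majority-vote rasters, correlation table, NDVI series, and a
run manifest)."""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from shapely.geometry import box

from . import __version__
from .accuracy import MapEvaluation, evaluate_map
from .agreement import (consensus_raster, consensus_summary, majority_vote,
                        mean_and_rank_matrices, order_by_resolution, pairwise_agreement)
from .correlates import masked_ndvi_series, metric_covariate_correlation
from .harmonize import clip_to_boundary, resample_to_grid
from .rasters import BinaryCropMap, GridSpec, MapMetadata
from .sampling import ReferenceDataset, ReferencePoint, consensus_filter, sample_uniform, summarize_dataset
from .synthetic import (SyntheticScenario, degrade_map, generate_interpreter_labels,
                        generate_ndvi_cube, generate_true_landscape)
from . import io as cmio

logger = logging.getLogger(__name__)

__all__ = ["RunConfig", "run_pipeline", "simulate_inputs"]


@dataclass(frozen=True)
class RunConfig:
    """Declarative run configuration.

    Exactly one of ``scenario`` (synthetic mode) or ``map_paths`` +
    ``boundary_path`` + ``points_path`` (file mode) must be set.
    """

    out_dir: str
    seed: int = 0
    scenario: SyntheticScenario | None = None
    map_paths: tuple[str, ...] = ()
    boundary_path: str | None = None
    points_path: str | None = None
    ndvi_path: str | None = None
    region: str = ""
    reference_year: int = 2019
    common_resolution: float | None = None
    majority_min_votes: int | None = None  # None = strict majority
    variance_mode: str = "as-printed"

    def __post_init__(self) -> None:
        synthetic = self.scenario is not None
        real = bool(self.map_paths)
        if synthetic == real:
            raise ValueError("exactly one of synthetic scenario or real map inputs must be set")
        if real and (self.boundary_path is None or self.points_path is None):
            raise ValueError("file mode requires boundary_path and points_path")
        if self.common_resolution is not None and self.common_resolution <= 0:
            raise ValueError("common resolution must be > 0")
        if self.variance_mode not in ("as-printed", "standard"):
            raise ValueError(f"unknown variance mode {self.variance_mode!r}")

    @classmethod
    def from_yaml(cls, path, **overrides) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        scenario = None
        if "scenario" in raw:
            scenario_val = raw.pop("scenario")
            if isinstance(scenario_val, str):
                scenario = cmio.read_scenario_config(Path(path).parent / scenario_val)
            else:
                raise ValueError("scenario must be a path to a flat scenario config file")
        for key, value in overrides.items():
            if key in raw and raw[key] != value:
                logger.info("config override: %s=%r (file had %r)", key, value, raw[key])
            raw[key] = value
        if "map_paths" in raw:
            raw["map_paths"] = tuple(raw["map_paths"])
        return cls(scenario=scenario, **raw)


def _child_seeds(seed: int, n: int) -> list[int]:
    state = np.random.SeedSequence(seed).generate_state(n, dtype=np.uint32)
    return [int(s & 0x7FFFFFFF) for s in state]


def simulate_inputs(scenario: SyntheticScenario, seed: int | None = None):
    """Generate the full set of study inputs for a synthetic scenario.

    Returns (truth, boundary polygon, product maps at native resolution,
    raw labeled points, NDVI cube).  Deterministic in (scenario, seed).
    """
    seed = scenario.seed if seed is None else seed
    truth = generate_true_landscape(scenario)
    boundary = box(*scenario.grid.bounds)

    seeds = _child_seeds(seed, len(scenario.products) + 1 + scenario.n_reference_points)
    products = [degrade_map(truth, spec, s)
                for spec, s in zip(scenario.products, seeds)]

    locs = sample_uniform(boundary, scenario.n_reference_points,
                          seeds[len(scenario.products)])
    label_seeds = seeds[len(scenario.products) + 1:]
    points = []
    for i, ((x, y), s) in enumerate(zip(locs, label_seeds)):
        row, col = truth.grid.cell_index(x, y)
        t = int(truth.values[int(row), int(col)])
        labels = generate_interpreter_labels(t, scenario.interpreters_per_point,
                                             scenario.label_noise_rate, s)
        points.append(ReferencePoint(
            id=f"pt-{i:05d}", lon=float(x), lat=float(y),
            interpreter_labels=labels, truth=t,
            validity_start=f"{scenario.reference_year}-01-01",
            validity_end=f"{scenario.reference_year}-12-31",
        ))
    cube = generate_ndvi_cube(scenario, truth)
    return truth, boundary, products, points, cube


def _harmonize_all(maps, target: GridSpec, boundary):
    return [clip_to_boundary(resample_to_grid(m, target), boundary) for m in maps]


def run_pipeline(config: RunConfig) -> dict:
    """Execute the full analysis and write the artifact bundle.

    Stages: simulate/load inputs → harmonise to the common grid → build the
    reference dataset → per-map and ensemble accuracy evaluation →
    consensus and pairwise-agreement analytics → accuracy-vs-covariate
    correlations → zonal NDVI series → manifest.  Any stage failure aborts
    with the stage name in the raised error.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "setup"
    try:
        stage = "inputs"
        if config.scenario is not None:
            scenario = config.scenario
            truth, boundary, native_maps, raw_points, cube = simulate_inputs(scenario, config.seed)
            region = scenario.region
            ref_year = scenario.reference_year
            target = scenario.grid
            dataset = consensus_filter(raw_points, region=region, year=ref_year)
            cmio.write_scenario_config(out / "scenario.cfg", scenario)
            cmio.write_points_csv(out / "reference_points_raw.csv", raw_points)
            scenario_echo = (out / "scenario.cfg").read_text()
        else:
            native_maps = [cmio.read_geotiff(p) for p in config.map_paths]
            boundary = cmio.read_boundary_geojson(config.boundary_path)
            loaded = cmio.read_points_geojson(config.points_path) \
                if str(config.points_path).endswith(".geojson") or str(config.points_path).endswith(".json") \
                else cmio.read_points_csv(config.points_path, region=config.region,
                                          year=config.reference_year)
            dataset = loaded
            region = config.region or dataset.region
            ref_year = config.reference_year
            res = config.common_resolution or min(m.grid.pixel_size for m in native_maps)
            g0 = native_maps[0].grid
            minx, miny, maxx, maxy = boundary.bounds
            target = GridSpec(g0.origin_x, g0.origin_y, res,
                              int(np.ceil((maxx - g0.origin_x) / res)),
                              int(np.ceil((g0.origin_y - miny) / res)), g0.crs)
            cube = cmio.read_ndvi_geotiff(config.ndvi_path) if config.ndvi_path else None
            scenario_echo = None
        logger.info("reference dataset: %d point(s) retained of %d",
                    len(dataset.points),
                    len(raw_points) if config.scenario is not None else len(dataset.points))

        stage = "harmonize"
        maps = order_by_resolution(_harmonize_all(native_maps, target, boundary))

        stage = "evaluate"
        evals: list[MapEvaluation] = [
            evaluate_map(m, dataset, config.variance_mode) for m in maps
        ]

        stage = "agreement"
        cr = consensus_raster(maps)
        summary = consensus_summary(cr)
        mv = majority_vote(cr, config.majority_min_votes)
        evals.append(evaluate_map(mv, dataset, config.variance_mode))
        agreement = pairwise_agreement(maps + [mv])
        mean_matrix, ranks = mean_and_rank_matrices([agreement])

        stage = "correlate"
        mean_metrics = {
            ev.map_name: {k: est.value for k, est in ev.metrics().items()}
            for ev in evals if ev.map_name != "majority-vote"
        }
        metadata = [m.metadata for m in maps if m.metadata]
        correlations = []
        for covariate in ("resolution", "temporal_mismatch"):
            try:
                correlations.extend(metric_covariate_correlation(
                    mean_metrics, metadata, covariate, reference_year=ref_year))
            except ValueError as exc:
                logger.warning("correlation vs %s skipped: %s", covariate, exc)

        stage = "ndvi"
        series = []
        if cube is not None:
            for m in maps + [mv]:
                mask = m if m.grid.same_geometry(cube.grid) else resample_to_grid(m, cube.grid)
                series.append(masked_ndvi_series(cube, mask, region=boundary,
                                                 mask_name=(m.metadata.name if m.metadata else "map"),
                                                 region_name=region))

        stage = "write"
        cmio.write_evaluations_csv(out / "evaluations.csv", evals)
        pd.DataFrame([{
            "region": region,
            "all_same_pct": summary.pct_all_same,
            "all_crop_pct": summary.pct_all_crop,
            "split_pct": summary.pct_split,
            "none_crop_pct": summary.pct_none_crop,
        }]).to_csv(out / "consensus_summary.csv", index=False)
        names = list(agreement.names)
        pd.DataFrame(agreement.matrix, index=names, columns=names).to_csv(out / "agreement_matrix.csv")
        pd.DataFrame(ranks, index=names, columns=names).to_csv(out / "agreement_ranks.csv")
        pd.DataFrame([{
            "metric": c.metric, "covariate": c.covariate, "r": c.r,
            "n_maps": c.n_maps, "excluded": ";".join(c.excluded),
        } for c in correlations]).to_csv(out / "correlations.csv", index=False)
        if series:
            pd.concat([pd.DataFrame({
                "date": s.dates, "mean_ndvi": s.values,
                "mask_name": s.mask_name, "region": s.region,
            }) for s in series]).to_csv(out / "ndvi_series.csv", index=False)
        cmio.write_geotiff(out / "consensus.tif",
                           BinaryCropMap(cr.grid, np.zeros(cr.grid.shape, np.uint8), cr.nodata),
                           values=cr.values.astype(np.uint8))
        cmio.write_geotiff(out / "majority_vote.tif", mv)
        cmio.write_points_geojson(out / "reference_points.geojson", dataset)
        cmio.write_points_csv(out / "reference_points.csv", dataset)

        manifest = {
            "version": __version__,
            "seed": config.seed,
            "variance_mode": config.variance_mode,
            "region": region,
            "reference_year": ref_year,
            "n_maps": len(maps),
            "dataset_summary": summarize_dataset(dataset),
            "scenario_echo": scenario_echo,
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=1))
    except Exception:
        logger.error("pipeline failed at stage %r", stage)
        raise

    return {
        "maps": maps,
        "dataset": dataset,
        "evaluations": evals,
        "consensus": cr,
        "consensus_summary": summary,
        "majority_vote": mv,
        "agreement": agreement,
        "agreement_ranks": ranks,
        "correlations": correlations,
        "ndvi_series": series,
        "out_dir": str(out),
    }
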