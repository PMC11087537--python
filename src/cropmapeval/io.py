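"""File round-trips for the pipeline's domain types.

Rasters travel as single- or multi-band GeoTIFFs: ``tifffile`` handles the
TIFF container and the georeferencing is carried in the standard GeoTIFF
tags (ModelPixelScale, ModelTiepoint) plus the GDAL nodata tag, with CRS and
map metadata in a JSON image description.  Points travel as GeoJSON
FeatureCollections or flat CSV; tables as CSV via pandas.
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile
from shapely.geometry import mapping as _geom_mapping, shape as _geom_shape

from .accuracy import MapEvaluation, MetricEstimate
from .rasters import BinaryCropMap, GridSpec, MapMetadata, NDVICube
from .sampling import ReferenceDataset, ReferencePoint, SampleDesign
from .synthetic import SyntheticScenario

__all__ = [
    "write_geotiff",
    "read_geotiff",
    "write_ndvi_geotiff",
    "read_ndvi_geotiff",
    "write_points_geojson",
    "read_points_geojson",
    "write_points_csv",
    "read_points_csv",
    "write_evaluations_csv",
    "read_evaluations_csv",
    "write_boundary_geojson",
    "read_boundary_geojson",
    "write_scenario_config",
    "read_scenario_config",
]

NODATA_BYTE = 255

_TAG_PIXEL_SCALE = 33550
_TAG_TIEPOINT = 33922
_TAG_GDAL_NODATA = 42113


def _geo_tags(grid: GridSpec, nodata_value) -> list[tuple]:
    s = float(grid.pixel_size)
    return [
        (_TAG_PIXEL_SCALE, "d", 3, (s, s, 0.0)),
        (_TAG_TIEPOINT, "d", 6, (0.0, 0.0, 0.0, float(grid.origin_x), float(grid.origin_y), 0.0)),
        (_TAG_GDAL_NODATA, "s", 0, str(nodata_value)),
    ]


def _grid_from_tags(page, shape_hw: tuple[int, int], crs: str) -> GridSpec:
    try:
        sx, sy, _ = page.tags[_TAG_PIXEL_SCALE].value
        tie = page.tags[_TAG_TIEPOINT].value
    except KeyError as exc:
        raise ValueError("TIFF lacks GeoTIFF georeferencing tags") from exc
    if abs(sx - sy) > 1e-12:
        raise ValueError("only square pixels are supported")
    ox, oy = float(tie[3]), float(tie[4])
    h, w = shape_hw
    return GridSpec(ox, oy, float(sx), w, h, crs)


def write_geotiff(path, cropmap: BinaryCropMap, values: np.ndarray | None = None) -> None:
    """Write a binary map (or an integer raster such as a consensus count,
    via ``values``) as a single-band GeoTIFF with nodata 255."""
    data = cropmap.values if values is None else np.asarray(values)
    out = data.astype(np.uint8, copy=True) if values is None else data.copy()
    if out.dtype == np.uint8:
        out[cropmap.nodata] = NODATA_BYTE
        nd = NODATA_BYTE
    else:
        out[cropmap.nodata] = -1
        nd = -1
    desc = {
        "crs": cropmap.grid.crs,
        "metadata": None if cropmap.metadata is None else {
            "name": cropmap.metadata.name,
            "native_resolution": cropmap.metadata.native_resolution,
            "nominal_year": cropmap.metadata.nominal_year,
        },
    }
    tifffile.imwrite(
        path, out,
        extratags=_geo_tags(cropmap.grid, nd),
        description=json.dumps(desc),
        photometric="minisblack",
    )


def read_geotiff(path) -> BinaryCropMap:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = page.asarray()
        desc = json.loads(page.tags["ImageDescription"].value) if "ImageDescription" in page.tags else {}
        grid = _grid_from_tags(page, data.shape, desc.get("crs", "local"))
    nodata = data == NODATA_BYTE
    values = np.where(nodata, 0, data).astype(np.uint8)
    md = desc.get("metadata")
    metadata = None if md is None else MapMetadata(md["name"], md["native_resolution"], md["nominal_year"])
    return BinaryCropMap(grid, values, nodata, metadata)


def write_ndvi_geotiff(path, cube: NDVICube) -> None:
    """Multi-band float GeoTIFF, one band per timestep, band dates in the
    JSON description."""
    desc = {"crs": cube.grid.crs, "dates": list(cube.dates)}
    tifffile.imwrite(
        path, cube.values.astype(np.float32),
        extratags=_geo_tags(cube.grid, "nan"),
        description=json.dumps(desc),
        photometric="minisblack",
    )


def read_ndvi_geotiff(path) -> NDVICube:
    with tifffile.TiffFile(path) as tif:
        page = tif.pages[0]
        data = tif.asarray()
        desc = json.loads(page.tags["ImageDescription"].value)
        if data.ndim == 2:
            data = data[None]
        grid = _grid_from_tags(page, data.shape[1:], desc.get("crs", "local"))
    return NDVICube(grid, desc["dates"], data.astype(float))


def _point_properties(p: ReferencePoint) -> dict:
    props: dict = {"id": p.id}
    for i, lab in enumerate(p.interpreter_labels, start=1):
        props[f"label_{i}"] = int(lab)
    props["final_label"] = p.final_label
    props["validity_start"] = p.validity_start
    props["validity_end"] = p.validity_end
    props["stratum"] = p.stratum
    props["truth"] = p.truth
    return props


def _point_from_properties(lon: float, lat: float, props: dict) -> ReferencePoint:
    labels = []
    i = 1
    while f"label_{i}" in props and props[f"label_{i}"] is not None and not (
        isinstance(props[f"label_{i}"], float) and np.isnan(props[f"label_{i}"])
    ):
        labels.append(int(props[f"label_{i}"]))
        i += 1

    def _opt(key, cast):
        v = props.get(key)
        if v is None or (isinstance(v, float) and np.isnan(v)):
            return None
        return cast(v)

    return ReferencePoint(
        id=str(props["id"]), lon=float(lon), lat=float(lat),
        interpreter_labels=tuple(labels),
        final_label=_opt("final_label", int),
        validity_start=_opt("validity_start", str),
        validity_end=_opt("validity_end", str),
        stratum=_opt("stratum", int),
        truth=_opt("truth", int),
    )


def write_points_geojson(path, dataset: ReferenceDataset | Sequence[ReferencePoint]) -> None:
    points = dataset.points if isinstance(dataset, ReferenceDataset) else dataset
    features = [
        {
            "type": "Feature",
            "geometry": {"type": "Point", "coordinates": [p.lon, p.lat]},
            "properties": _point_properties(p),
        }
        for p in points
    ]
    fc: dict = {"type": "FeatureCollection", "features": features}
    if isinstance(dataset, ReferenceDataset):
        fc["properties"] = {"region": dataset.region, "year": dataset.year,
                            "design": dataset.design.variant}
    Path(path).write_text(json.dumps(fc, indent=1))


def read_points_geojson(path, raw: bool = False):
    """Read a point file; ``raw=True`` returns the bare point list (for
    pre-filter label files), otherwise a :class:`ReferenceDataset`."""
    fc = json.loads(Path(path).read_text())
    if fc.get("type") != "FeatureCollection":
        raise ValueError(f"{path}: not a GeoJSON FeatureCollection")
    points = []
    for i, feat in enumerate(fc["features"]):
        geom = feat.get("geometry") or {}
        if geom.get("type") != "Point":
            raise ValueError(f"{path}: feature {i} is not a Point")
        lon, lat = geom["coordinates"][:2]
        points.append(_point_from_properties(lon, lat, feat["properties"]))
    if raw:
        return points
    meta = fc.get("properties", {})
    design = SampleDesign(meta.get("design", "uniform"))
    return ReferenceDataset(
        region=meta.get("region", ""), year=int(meta.get("year", 0)),
        points=tuple(points), design=design,
    )


def write_points_csv(path, dataset: ReferenceDataset | Sequence[ReferencePoint]) -> None:
    points = dataset.points if isinstance(dataset, ReferenceDataset) else dataset
    rows = []
    for p in points:
        row = {"id": p.id, "lon": p.lon, "lat": p.lat}
        row.update({k: v for k, v in _point_properties(p).items() if k != "id"})
        rows.append(row)
    # %.17g keeps coordinates bit-exact through the round trip
    pd.DataFrame(rows).to_csv(path, index=False, float_format="%.17g")


def read_points_csv(path, region: str = "", year: int = 0, raw: bool = False):
    df = pd.read_csv(path, float_precision="round_trip")
    points = tuple(
        _point_from_properties(row["lon"], row["lat"], row.to_dict())
        for _, row in df.iterrows()
    )
    if raw:
        return list(points)
    return ReferenceDataset(region=region, year=year, points=points)


_EVAL_METRICS = ("accuracy", "precision", "recall", "f1")


def write_evaluations_csv(path, evals: Sequence[MapEvaluation]) -> None:
    """Long-format metric table: map, region, metric, value, se plus
    2-decimal display columns."""
    rows = []
    for ev in evals:
        for metric, est in ev.metrics().items():
            v, s = est.rounded()
            rows.append({
                "map": ev.map_name, "region": ev.region, "metric": metric,
                "value": est.value, "se": est.se,
                "value_2dp": f"{v:.2f}", "se_2dp": f"{s:.2f}",
            })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_evaluations_csv(path) -> list[MapEvaluation]:
    df = pd.read_csv(path)
    evals = []
    for (map_name, region), grp in df.groupby(["map", "region"], sort=False):
        ests = {row["metric"]: MetricEstimate(row["value"], row["se"])
                for _, row in grp.iterrows()}
        missing = set(_EVAL_METRICS) - set(ests)
        if missing:
            raise ValueError(f"{path}: map {map_name!r} missing metrics {sorted(missing)}")
        evals.append(MapEvaluation(map_name, region, ests["accuracy"],
                                   ests["precision"], ests["recall"], ests["f1"]))
    return evals


def write_boundary_geojson(path, polygon) -> None:
    Path(path).write_text(json.dumps({
        "type": "Feature", "geometry": _geom_mapping(polygon), "properties": {},
    }))


def read_boundary_geojson(path):
    obj = json.loads(Path(path).read_text())
    if obj.get("type") == "Feature":
        obj = obj["geometry"]
    elif obj.get("type") == "FeatureCollection":
        obj = obj["features"][0]["geometry"]
    return _geom_shape(obj)


def write_scenario_config(path, scenario: SyntheticScenario) -> None:
    """Flat key=value scenario file, echoed verbatim into run manifests."""
    g, p = scenario.grid, scenario.ndvi_params
    lines = [
        f"seed={scenario.seed}",
        f"region={scenario.region}",
        f"reference_year={scenario.reference_year}",
        f"grid.origin_x={g.origin_x}",
        f"grid.origin_y={g.origin_y}",
        f"grid.pixel_size={g.pixel_size}",
        f"grid.width={g.width}",
        f"grid.height={g.height}",
        f"grid.crs={g.crs}",
        f"crop_fraction={scenario.crop_fraction}",
        f"smoothing_sigma={scenario.smoothing_sigma}",
        f"n_reference_points={scenario.n_reference_points}",
        f"interpreters_per_point={scenario.interpreters_per_point}",
        f"label_noise_rate={scenario.label_noise_rate}",
        f"ndvi.crop_baseline={p.crop_baseline}",
        f"ndvi.crop_amplitude={p.crop_amplitude}",
        f"ndvi.noncrop_baseline={p.noncrop_baseline}",
        f"ndvi.noncrop_amplitude={p.noncrop_amplitude}",
        f"ndvi.noise_sd={p.noise_sd}",
        f"ndvi.n_timesteps={p.n_timesteps}",
    ]
    for i, prod in enumerate(scenario.products):
        lines.append(
            f"product.{i}={prod.name},{prod.native_resolution},{prod.nominal_year},"
            f"{prod.omission_rate},{prod.commission_rate}"
        )
    Path(path).write_text("\n".join(lines) + "\n")


def read_scenario_config(path) -> SyntheticScenario:
    from .synthetic import NDVIParams, ProductSpec

    kv: dict[str, str] = {}
    products = []
    for lineno, line in enumerate(Path(path).read_text().splitlines(), start=1):
        line = line.strip()
        if not line or line.startswith("#"):
            continue
        if "=" not in line:
            raise ValueError(f"{path}:{lineno}: expected key=value, got {line!r}")
        key, value = line.split("=", 1)
        if key.startswith("product."):
            name, res, year, om, com = value.split(",")
            products.append(ProductSpec(name, float(res), int(year), float(om), float(com)))
        else:
            kv[key] = value
    grid = GridSpec(
        float(kv["grid.origin_x"]), float(kv["grid.origin_y"]),
        float(kv["grid.pixel_size"]), int(kv["grid.width"]),
        int(kv["grid.height"]), kv.get("grid.crs", "local"),
    )
    ndvi = NDVIParams(
        crop_baseline=float(kv["ndvi.crop_baseline"]),
        crop_amplitude=float(kv["ndvi.crop_amplitude"]),
        noncrop_baseline=float(kv["ndvi.noncrop_baseline"]),
        noncrop_amplitude=float(kv["ndvi.noncrop_amplitude"]),
        noise_sd=float(kv["ndvi.noise_sd"]),
        n_timesteps=int(kv["ndvi.n_timesteps"]),
    )
    return SyntheticScenario(
        seed=int(kv["seed"]),
        grid=grid,
        crop_fraction=float(kv["crop_fraction"]),
        products=tuple(products),
        n_reference_points=int(kv["n_reference_points"]),
        interpreters_per_point=int(kv["interpreters_per_point"]),
        label_noise_rate=float(kv["label_noise_rate"]),
        ndvi_params=ndvi,
        smoothing_sigma=float(kv["smoothing_sigma"]),
        region=kv.get("region", "synthetic"),
        reference_year=int(kv.get("reference_year", 2019)),
    )
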