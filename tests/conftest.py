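import numpy as np
import pytest
from shapely.geometry import box

from cropmapeval import (
    BinaryCropMap,
    GridSpec,
    MapMetadata,
    ReferenceDataset,
    ReferencePoint,
)


@pytest.fixture
def small_grid() -> GridSpec:
    """10x10 grid of 10-unit pixels with upper-left corner at (0, 100)."""
    return GridSpec(0.0, 100.0, 10.0, 10, 10)


@pytest.fixture
def unit_square():
    return box(0.0, 0.0, 1.0, 1.0)


def make_map(values, grid=None, nodata=None, name="map", resolution=None, year=2019):
    values = np.asarray(values, dtype=np.uint8)
    h, w = values.shape
    if grid is None:
        grid = GridSpec(0.0, float(h), 1.0, w, h)
    if nodata is None:
        nodata = np.zeros((h, w), dtype=bool)
    meta = MapMetadata(name, resolution or grid.pixel_size, year)
    return BinaryCropMap(grid, values, np.asarray(nodata, dtype=bool), meta)


def make_dataset(n_crop, n_non_crop, cropmap, region="test", year=2019):
    """Reference points with unanimous labels placed on distinct cell
    centers of a map's grid: first ``n_crop`` crop, rest non-crop."""
    grid = cropmap.grid
    total = n_crop + n_non_crop
    if total > grid.n_pixels:
        raise ValueError("more points than cells")
    cx, cy = grid.cell_centers()
    xs, ys = cx.ravel()[:total], cy.ravel()[:total]
    points = []
    for i, (x, y) in enumerate(zip(xs, ys)):
        label = 1 if i < n_crop else 0
        points.append(ReferencePoint(
            id=f"p{i}", lon=float(x), lat=float(y),
            interpreter_labels=(label, label), final_label=label,
        ))
    return ReferenceDataset(region=region, year=year, points=tuple(points))


@pytest.fixture
def mali_fixture():
    """Worked example: 10 crop + 437 non-crop reference points and a map
    that predicts non-crop everywhere."""
    grid = GridSpec(0.0, 300.0, 10.0, 30, 30)
    cropmap = make_map(np.zeros((30, 30)), grid=grid, name="esri-like", resolution=10)
    dataset = make_dataset(10, 437, cropmap, region="Mali", year=2019)
    return cropmap, dataset
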