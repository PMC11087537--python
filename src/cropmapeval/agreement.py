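"""Multi-map consensus analytics: per-pixel vote counts, consensus summary
percentages, pairwise agreement and rank matrices, and the majority-vote
ensemble.

A pixel enters the consensus statistics only if *every* constituent map is
valid there; otherwise vote counts would not be comparable across pixels.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

from .rasters import BinaryCropMap, GridSpec, MapMetadata

__all__ = [
    "ConsensusRaster",
    "ConsensusSummary",
    "AgreementMatrix",
    "order_by_resolution",
    "consensus_raster",
    "consensus_summary",
    "pairwise_agreement",
    "mean_and_rank_matrices",
    "majority_vote",
]


@dataclass
class ConsensusRaster:
    """Per-pixel count (0..K) of maps voting crop."""

    grid: GridSpec
    values: np.ndarray
    n_maps: int
    nodata: np.ndarray

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.int32)
        self.nodata = np.asarray(self.nodata, dtype=bool)
        if self.values.shape != self.grid.shape or self.nodata.shape != self.grid.shape:
            raise ValueError("consensus raster shape mismatch")
        valid = self.values[~self.nodata]
        if valid.size and (valid.min() < 0 or valid.max() > self.n_maps):
            raise ValueError("vote counts must lie in [0, K]")


@dataclass(frozen=True)
class ConsensusSummary:
    """Percentages of valid pixels in each agreement regime.

    ``pct_all_same`` = ``pct_all_crop`` + ``pct_none_crop`` exactly;
    ``pct_split`` covers the two central vote counts (e.g. 5 or 6 of 11).
    """

    pct_all_same: float
    pct_all_crop: float
    pct_split: float
    pct_none_crop: float


@dataclass(frozen=True)
class AgreementMatrix:
    """Symmetric K x K matrix of pairwise agreement fractions; the diagonal
    is set to 0 by convention.  Maps are ordered by native resolution, fine
    to coarse."""

    matrix: np.ndarray
    names: tuple[str, ...]

    def __post_init__(self) -> None:
        m = np.asarray(self.matrix, dtype=float)
        object.__setattr__(self, "matrix", m)
        k = len(self.names)
        if m.shape != (k, k):
            raise ValueError("matrix shape must match the number of map names")


def order_by_resolution(maps: Sequence[BinaryCropMap]) -> list[BinaryCropMap]:
    """Fine-to-coarse native resolution; ties broken by name."""
    def key(m: BinaryCropMap):
        md = m.metadata or MapMetadata("map", m.grid.pixel_size, 0)
        return (md.native_resolution, md.name)
    return sorted(maps, key=key)


def _check_common_grid(maps: Sequence[BinaryCropMap]) -> GridSpec:
    if len(maps) < 2:
        raise ValueError("need at least two maps")
    grid = maps[0].grid
    for m in maps[1:]:
        if not m.grid.same_geometry(grid):
            raise ValueError("all maps must share one grid")
    return grid


def consensus_raster(maps: Sequence[BinaryCropMap]) -> ConsensusRaster:
    """Per-pixel number of maps voting crop; nodata wherever any map is."""
    grid = _check_common_grid(maps)
    votes = np.zeros(grid.shape, dtype=np.int32)
    nodata = np.zeros(grid.shape, dtype=bool)
    for m in maps:
        votes += m.values
        nodata |= m.nodata
    votes[nodata] = 0
    return ConsensusRaster(grid, votes, len(maps), nodata)


def consensus_summary(cr: ConsensusRaster) -> ConsensusSummary:
    """Percentages of valid pixels that are unanimous crop, unanimous
    non-crop, unanimous either way, or split between the two central vote
    counts."""
    v = cr.values[~cr.nodata]
    if v.size == 0:
        raise ValueError("consensus raster has no valid pixels")
    K = cr.n_maps
    pct = lambda mask: float(100.0 * mask.sum() / v.size)
    all_crop = pct(v == K)
    none_crop = pct(v == 0)
    split_counts = {K // 2, -(-K // 2)} - {0, K}
    split = pct(np.isin(v, sorted(split_counts)))
    return ConsensusSummary(
        pct_all_same=all_crop + none_crop,
        pct_all_crop=all_crop,
        pct_split=split,
        pct_none_crop=none_crop,
    )


def pairwise_agreement(maps: Sequence[BinaryCropMap]) -> AgreementMatrix:
    """Fraction of jointly valid pixels where each pair of maps predicts
    the same class; diagonal forced to 0.  Input order is preserved — call
    :func:`order_by_resolution` first for the conventional ordering."""
    _check_common_grid(maps)
    K = len(maps)
    valid = ~np.logical_or.reduce([m.nodata for m in maps])
    if not valid.any():
        raise ValueError("maps share no valid pixels")
    stack = np.stack([m.values[valid] for m in maps]).astype(np.int8)
    out = np.zeros((K, K))
    for i in range(K):
        for j in range(i + 1, K):
            frac = float((stack[i] == stack[j]).mean())
            out[i, j] = out[j, i] = frac
    names = tuple((m.metadata.name if m.metadata else f"map{i}") for i, m in enumerate(maps))
    return AgreementMatrix(out, names)


def mean_and_rank_matrices(matrices: Sequence[AgreementMatrix]) -> tuple[AgreementMatrix, np.ndarray]:
    """Element-wise mean of per-region agreement matrices, plus per-row
    ranks (1 = lowest agreement) over off-diagonal entries; ties go to the
    lower column index.  Rank-matrix diagonal is 0."""
    if not matrices:
        raise ValueError("no matrices given")
    names = matrices[0].names
    K = len(names)
    for m in matrices:
        if m.matrix.shape != (K, K) or m.names != names:
            raise ValueError("matrices must share shape and map ordering")
    mean = np.mean([m.matrix for m in matrices], axis=0)

    ranks = np.zeros((K, K), dtype=int)
    for i in range(K):
        cols = [j for j in range(K) if j != i]
        order = sorted(cols, key=lambda j: (mean[i, j], j))  # stable tie-break
        for rank, j in enumerate(order, start=1):
            ranks[i, j] = rank
    return AgreementMatrix(mean, names), ranks


def majority_vote(cr: ConsensusRaster, min_votes: int | None = None) -> BinaryCropMap:
    """Ensemble map: crop iff strictly more than half the maps vote crop
    (for 11 maps, 6 or more).  ``min_votes`` overrides the threshold; an
    even-K exact tie is non-crop under the default."""
    if min_votes is None:
        values = (2 * cr.values > cr.n_maps).astype(np.uint8)
    else:
        values = (cr.values >= min_votes).astype(np.uint8)
    values[cr.nodata] = 0
    meta = MapMetadata("majority-vote", cr.grid.pixel_size, 0)
    return BinaryCropMap(cr.grid, values, cr.nodata.copy(), meta)
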