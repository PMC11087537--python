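"""Design-based map accuracy estimation from a sample confusion matrix and
mapped-area weights.

The estimators follow the good-practice framework of Stehman & Foody for
probability-sampled reference data.  The sample confusion matrix ``C`` (rows
= map class, columns = reference class) is re-expressed as a *population
error matrix* ``E`` of area proportions using the per-class mapped-area
weights ``W``:

    p_ij = W_i * C_ij / C_i.

so that overall accuracy, user's accuracy (precision) and producer's
accuracy (recall) computed from ``E`` estimate the corresponding population
quantities over the mapped area rather than over the sample.  Each metric is
paired with a standard error from the matching stratified-sampling variance
estimator; the F1 score's standard error is obtained by propagating the UA
and PA errors through the harmonic mean (relative errors of the numerator
and denominator added, since they are not independent).

Classes are binary throughout: index 0 = non-crop, index 1 = crop.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import TYPE_CHECKING

import numpy as np

if TYPE_CHECKING:  # pragma: no cover - import cycle guard
    from .rasters import BinaryCropMap
    from .sampling import ReferenceDataset

logger = logging.getLogger(__name__)

__all__ = [
    "ConfusionMatrix",
    "MappedAreaSummary",
    "AreaWeights",
    "PopulationErrorMatrix",
    "MetricEstimate",
    "MapEvaluation",
    "build_confusion",
    "population_matrix",
    "overall_accuracy",
    "users_accuracy",
    "producers_accuracy",
    "variance_oa",
    "variance_ua",
    "variance_pa",
    "f1_with_error",
    "evaluate_map",
]

_PROP_TOL = 1e-12


@dataclass(frozen=True)
class ConfusionMatrix:
    """Sample confusion matrix ``C = [[TN, FN], [FP, TP]]``.

    Row 0 holds points the map called non-crop, row 1 points it called crop;
    columns index the reference label in the same order.
    """

    tn: int
    fn: int
    fp: int
    tp: int

    def __post_init__(self) -> None:
        if min(self.tn, self.fn, self.fp, self.tp) < 0:
            raise ValueError("confusion counts must be non-negative")

    def as_array(self) -> np.ndarray:
        return np.array([[self.tn, self.fn], [self.fp, self.tp]], dtype=float)

    @property
    def row_sums(self) -> np.ndarray:
        """C_i. — points per *map* class."""
        return self.as_array().sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        """C_.j — points per *reference* class."""
        return self.as_array().sum(axis=0)

    @property
    def total(self) -> int:
        return self.tn + self.fn + self.fp + self.tp


@dataclass(frozen=True)
class MappedAreaSummary:
    """Total mapped area per class, in pixels: A = [n_neg, n_pos]."""

    n_neg: int
    n_pos: int

    def __post_init__(self) -> None:
        if self.n_neg < 0 or self.n_pos < 0:
            raise ValueError("pixel counts must be non-negative")
        if self.n == 0:
            raise ValueError("map has no valid pixels")

    @property
    def n(self) -> int:
        return self.n_neg + self.n_pos

    def as_array(self) -> np.ndarray:
        return np.array([self.n_neg, self.n_pos], dtype=float)


@dataclass(frozen=True)
class AreaWeights:
    """Proportion of mapped area in each class: W = A / n."""

    w_neg: float
    w_pos: float

    def __post_init__(self) -> None:
        for w in (self.w_neg, self.w_pos):
            if not (-_PROP_TOL <= w <= 1 + _PROP_TOL):
                raise ValueError("weights must lie in [0, 1]")
        if abs(self.w_neg + self.w_pos - 1.0) > _PROP_TOL:
            raise ValueError("weights must sum to 1")

    @classmethod
    def from_mapped_area(cls, area: MappedAreaSummary) -> "AreaWeights":
        return cls(area.n_neg / area.n, area.n_pos / area.n)

    def as_array(self) -> np.ndarray:
        return np.array([self.w_neg, self.w_pos], dtype=float)


@dataclass(frozen=True)
class PopulationErrorMatrix:
    """2x2 matrix of area proportions p_ij; rows sum to the area weights."""

    p: np.ndarray

    def __post_init__(self) -> None:
        p = np.asarray(self.p, dtype=float)
        object.__setattr__(self, "p", p)
        if p.shape != (2, 2):
            raise ValueError("population error matrix must be 2x2")
        if (p < -_PROP_TOL).any():
            raise ValueError("area proportions must be non-negative")
        if abs(p.sum() - 1.0) > 1e-9:
            raise ValueError("area proportions must sum to 1")

    @property
    def row_sums(self) -> np.ndarray:
        """p_i. — equals the area weights W by construction."""
        return self.p.sum(axis=1)

    @property
    def col_sums(self) -> np.ndarray:
        """p_.j — estimated area proportion of each reference class."""
        return self.p.sum(axis=0)


@dataclass(frozen=True)
class MetricEstimate:
    """A point estimate in [0, 1] with its standard error."""

    value: float
    se: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 - 1e-9 <= self.value <= 1.0 + 1e-9):
            raise ValueError("metric value must lie in [0, 1]")
        if self.se < 0:
            raise ValueError("standard error must be non-negative")

    def rounded(self, ndigits: int = 2) -> tuple[float, float]:
        return (round(self.value, ndigits), round(self.se, ndigits))

    def __format__(self, spec: str) -> str:
        v, s = self.rounded()
        return f"{v:.2f} ± {s:.2f}"


@dataclass(frozen=True)
class MapEvaluation:
    """OA / UA / PA / F1 (each with SE) for one map against one region's
    reference dataset."""

    map_name: str
    region: str
    oa: MetricEstimate
    ua_crop: MetricEstimate
    pa_crop: MetricEstimate
    f1_crop: MetricEstimate

    def metrics(self) -> dict[str, MetricEstimate]:
        return {
            "accuracy": self.oa,
            "precision": self.ua_crop,
            "recall": self.pa_crop,
            "f1": self.f1_crop,
        }


def build_confusion(dataset: "ReferenceDataset", cropmap: "BinaryCropMap") -> ConfusionMatrix:
    """Tally (map value, reference label) pairs over the retained points.

    Points falling on nodata pixels (or outside the map extent) are dropped
    with a logged count.  Raises if no usable point remains.
    """
    pts = [p for p in dataset.points if p.final_label is not None]
    if not pts:
        raise ValueError("reference dataset has no retained points")
    xs = np.array([p.lon for p in pts])
    ys = np.array([p.lat for p in pts])
    labels = np.array([p.final_label for p in pts], dtype=int)

    row, col = cropmap.grid.cell_index(xs, ys)
    inside = cropmap.grid.contains(row, col)
    usable = inside.copy()
    usable[inside] &= ~cropmap.nodata[row[inside], col[inside]]
    n_dropped = int((~usable).sum())
    if n_dropped:
        logger.info("build_confusion: dropped %d point(s) on nodata/outside pixels", n_dropped)
    if not usable.any():
        raise ValueError("no reference point falls on a valid map pixel")

    mapped = cropmap.values[row[usable], col[usable]].astype(int)
    ref = labels[usable]
    counts = np.zeros((2, 2), dtype=int)
    np.add.at(counts, (mapped, ref), 1)
    return ConfusionMatrix(
        tn=int(counts[0, 0]), fn=int(counts[0, 1]),
        fp=int(counts[1, 0]), tp=int(counts[1, 1]),
    )


def population_matrix(C: ConfusionMatrix, W: AreaWeights) -> PopulationErrorMatrix:
    """Area-weight the confusion matrix: p_ij = W_i * C_ij / C_i. .

    Rows with zero area weight contribute nothing regardless of their sample
    counts; a mapped class (W_i > 0) with no sample points is an error — no
    data exist to estimate its error rates.
    """
    c = C.as_array()
    w = W.as_array()
    rows = C.row_sums
    p = np.zeros((2, 2))
    for i in range(2):
        if w[i] == 0.0:
            continue
        if rows[i] == 0:
            raise ValueError(f"map class {i} has positive area weight but no sample points")
        p[i] = w[i] * c[i] / rows[i]
    return PopulationErrorMatrix(p)


def overall_accuracy(E: PopulationErrorMatrix) -> float:
    """OA = sum of diagonal area proportions."""
    return float(np.trace(E.p))


def users_accuracy(E: PopulationErrorMatrix, class_index: int = 1) -> float:
    """User's accuracy (precision) P_i = p_ii / p_i. ; 0 if the class was
    never mapped (zero row sum)."""
    denom = E.row_sums[class_index]
    return float(E.p[class_index, class_index] / denom) if denom > 0 else 0.0


def producers_accuracy(E: PopulationErrorMatrix, class_index: int = 1) -> float:
    """Producer's accuracy (recall) R_j = p_jj / p_.j ; 0 if the reference
    class has zero estimated area."""
    denom = E.col_sums[class_index]
    return float(E.p[class_index, class_index] / denom) if denom > 0 else 0.0


def _sample_ua(C: ConfusionMatrix) -> np.ndarray:
    """Within-row sample proportions correct: P_i = C_ii / C_i. (0 if empty)."""
    c = C.as_array()
    rows = C.row_sums
    out = np.zeros(2)
    for i in range(2):
        if rows[i] > 0:
            out[i] = c[i, i] / rows[i]
    return out


def _check_row_support(C: ConfusionMatrix, W: AreaWeights, needed: list[int]) -> bool:
    """True if every needed row has >= 2 samples; otherwise warn once."""
    rows = C.row_sums
    w = W.as_array()
    for i in needed:
        if w[i] > 0 and rows[i] < 2:
            logger.warning(
                "variance undefined: map class %d has %d sample(s); SE reported as 0",
                i, int(rows[i]),
            )
            return False
    return True


def variance_oa(C: ConfusionMatrix, W: AreaWeights) -> float:
    """V(OA) = sum_i W_i^2 P_i (1 - P_i) / (C_i. - 1), stratified by map class."""
    if not _check_row_support(C, W, [0, 1]):
        return 0.0
    w = W.as_array()
    rows = C.row_sums
    P = _sample_ua(C)
    v = 0.0
    for i in range(2):
        if w[i] > 0:
            v += w[i] ** 2 * P[i] * (1 - P[i]) / (rows[i] - 1)
    return v


def variance_ua(C: ConfusionMatrix, W: AreaWeights, class_index: int = 1,
                mode: str = "as-printed") -> float:
    """Variance of user's accuracy for one map class.

    ``mode="as-printed"`` keeps the W_i^2 factor of the published form;
    ``mode="standard"`` uses the plain within-stratum binomial form
    P_i(1-P_i)/(C_i.-1) common in the accuracy-assessment literature.
    """
    if mode not in ("as-printed", "standard"):
        raise ValueError(f"unknown variance mode {mode!r}")
    w = W.as_array()[class_index]
    rows = C.row_sums[class_index]
    if w == 0.0 or rows == 0:
        return 0.0
    if not _check_row_support(C, W, [class_index]):
        return 0.0
    P = _sample_ua(C)[class_index]
    base = P * (1 - P) / (rows - 1)
    return (w ** 2) * base if mode == "as-printed" else base


def variance_pa(C: ConfusionMatrix, W: AreaWeights, A: MappedAreaSummary,
                class_index: int = 1) -> float:
    """Variance of producer's accuracy for reference class j.

    With N̂_.j = sum_i (A_i / C_i.) C_ij the estimated pixel total of
    reference class j:

        V(R_j) = [ A_j^2 (1-R_j)^2 P_j (1-P_j) / (C_j. - 1)
                   + R_j^2 * sum_{i≠j} A_i^2 (C_ij/C_i.)(1 - C_ij/C_i.)
                                        / (C_i. - 1) ] / N̂_.j^2
    """
    j = class_index
    c = C.as_array()
    rows = C.row_sums
    a = A.as_array()

    contributing = [i for i in range(2) if rows[i] > 0]
    if not contributing:
        return 0.0
    n_hat = sum((a[i] / rows[i]) * c[i, j] for i in contributing)
    if n_hat == 0:
        return 0.0
    if not _check_row_support(C, W, [0, 1]):
        return 0.0

    E = population_matrix(C, W)
    R = producers_accuracy(E, j)
    P = _sample_ua(C)

    term1 = 0.0
    if rows[j] > 1:
        term1 = a[j] ** 2 * (1 - R) ** 2 * P[j] * (1 - P[j]) / (rows[j] - 1)
    term2 = 0.0
    for i in range(2):
        if i == j or rows[i] <= 1:
            continue
        q = c[i, j] / rows[i]
        term2 += a[i] ** 2 * q * (1 - q) / (rows[i] - 1)
    return (term1 + R ** 2 * term2) / n_hat ** 2


def f1_with_error(P: MetricEstimate, R: MetricEstimate) -> MetricEstimate:
    """F1 = 2PR/(P+R) with its propagated standard error.

    Writing F1 = X/Y with X = 2PR and Y = P+R, the relative errors of X and
    Y add (they share the same inputs and are not independent):

        ΔF1 = 2(RΔP + PΔR)/(P+R) + 2PR(ΔP + ΔR)/(P+R)^2

    Degenerate case P + R = 0 returns F1 = 0 ± 0.
    """
    if P.se < 0 or R.se < 0:  # MetricEstimate enforces this; belt and braces
        raise ValueError("standard errors must be non-negative")
    p, r = P.value, R.value
    denom = p + r
    if denom == 0:
        return MetricEstimate(0.0, 0.0)
    f1 = 2 * p * r / denom
    # second term written as F1*(ΔP+ΔR)/(P+R) so a tiny denominator cannot
    # underflow when squared
    df1 = 2 * (r * P.se + p * R.se) / denom + f1 * (P.se + R.se) / denom
    return MetricEstimate(f1, df1)


def evaluate_map(cropmap: "BinaryCropMap", dataset: "ReferenceDataset",
                 variance_mode: str = "as-printed") -> MapEvaluation:
    """Full evaluation chain for one map: confusion matrix → area weights →
    population error matrix → OA/UA/PA/F1 with standard errors."""
    from .harmonize import mapped_area  # local import to avoid cycle

    C = build_confusion(dataset, cropmap)
    A = mapped_area(cropmap)
    W = AreaWeights.from_mapped_area(A)
    E = population_matrix(C, W)

    oa = MetricEstimate(overall_accuracy(E), np.sqrt(variance_oa(C, W)))
    ua = MetricEstimate(users_accuracy(E, 1), np.sqrt(variance_ua(C, W, 1, variance_mode)))
    pa = MetricEstimate(producers_accuracy(E, 1), np.sqrt(variance_pa(C, W, A, 1)))
    f1 = f1_with_error(ua, pa)

    name = cropmap.metadata.name if cropmap.metadata else "map"
    return MapEvaluation(
        map_name=name,
        region=dataset.region,
        oa=oa, ua_crop=ua, pa_crop=pa, f1_crop=f1,
    )
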