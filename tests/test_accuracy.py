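"""Area-weighted accuracy estimators: hand-checked arithmetic, degenerate
cases, the F1 error propagation, and distributional invariants."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from conftest import make_dataset, make_map
from cropmapeval import (
    AreaWeights,
    ConfusionMatrix,
    MappedAreaSummary,
    MetricEstimate,
    build_confusion,
    evaluate_map,
    f1_with_error,
    overall_accuracy,
    population_matrix,
    producers_accuracy,
    users_accuracy,
    variance_oa,
    variance_pa,
    variance_ua,
)

C_EX = ConfusionMatrix(tn=90, fn=10, fp=20, tp=80)
W_EX = AreaWeights(0.7, 0.3)


class TestBuildConfusion:
    def test_all_non_crop_map(self, mali_fixture):
        cropmap, dataset = mali_fixture
        C = build_confusion(dataset, cropmap)
        assert (C.tn, C.fn, C.fp, C.tp) == (437, 10, 0, 0)

    def test_perfect_map_has_no_errors(self):
        # points on every cell, labels equal to the map itself
        rng = np.random.default_rng(0)
        m = make_map(rng.integers(0, 2, (10, 10)))
        from cropmapeval import ReferenceDataset, ReferencePoint
        cx, cy = m.grid.cell_centers()
        pts = tuple(
            ReferencePoint(id=str(i), lon=float(x), lat=float(y),
                           interpreter_labels=(v, v), final_label=int(v))
            for i, (x, y, v) in enumerate(zip(cx.ravel(), cy.ravel(),
                                              m.values.ravel()))
        )
        C = build_confusion(ReferenceDataset("r", 2019, pts), m)
        assert C.fn == 0 and C.fp == 0 and C.total == 100

    def test_matches_per_point_tally(self):
        rng = np.random.default_rng(1)
        m = make_map(rng.integers(0, 2, (8, 8)))
        ds = make_dataset(20, 30, m)
        C = build_confusion(ds, m)
        counts = np.zeros((2, 2), int)
        for p in ds.points:
            r, c = m.grid.cell_index(p.lon, p.lat)
            counts[int(m.values[int(r), int(c)]), p.final_label] += 1
        assert C.as_array().astype(int).tolist() == counts.tolist()

    def test_points_on_nodata_dropped(self):
        m = make_map([[1, 0], [0, 1]], nodata=[[True, False], [False, False]])
        ds = make_dataset(1, 3, m)
        C = build_confusion(ds, m)
        assert C.total == 3


class TestPopulationMatrix:
    def test_hand_arithmetic(self):
        E = population_matrix(C_EX, W_EX)
        np.testing.assert_allclose(E.p, [[0.63, 0.07], [0.06, 0.24]])

    def test_reduces_to_sample_proportions(self):
        W = AreaWeights(100 / 200, 100 / 200)  # W_i = C_i./n
        E = population_matrix(C_EX, W)
        np.testing.assert_allclose(E.p, C_EX.as_array() / 200)

    def test_mali_worked_example(self):
        C = ConfusionMatrix(tn=437, fn=10, fp=0, tp=0)
        E = population_matrix(C, AreaWeights(1.0, 0.0))
        np.testing.assert_allclose(E.p, [[437 / 447, 10 / 447], [0, 0]])

    def test_weighted_class_without_samples_rejected(self):
        with pytest.raises(ValueError):
            population_matrix(ConfusionMatrix(10, 2, 0, 0), AreaWeights(0.6, 0.4))


class TestPointMetrics:
    def test_overall_accuracy_hand_values(self):
        E = population_matrix(C_EX, W_EX)
        assert overall_accuracy(E) == pytest.approx(0.87)
        mali = population_matrix(ConfusionMatrix(437, 10, 0, 0), AreaWeights(1, 0))
        assert overall_accuracy(mali) == pytest.approx(437 / 447)
        assert round(overall_accuracy(mali), 2) == 0.98

    def test_ua_pa_hand_values(self):
        E = population_matrix(C_EX, W_EX)
        assert users_accuracy(E, 1) == pytest.approx(0.24 / 0.30)
        assert producers_accuracy(E, 1) == pytest.approx(0.24 / 0.31)

    def test_degenerate_class_reports_zero(self):
        mali = population_matrix(ConfusionMatrix(437, 10, 0, 0), AreaWeights(1, 0))
        assert users_accuracy(mali, 1) == 0.0
        assert producers_accuracy(mali, 1) == 0.0

    def test_perfect_diagonal(self):
        E = population_matrix(ConfusionMatrix(50, 0, 0, 50), AreaWeights(0.5, 0.5))
        assert overall_accuracy(E) == 1.0
        for i in (0, 1):
            assert users_accuracy(E, i) == 1.0 and producers_accuracy(E, i) == 1.0


class TestVariances:
    def test_vanish_when_rows_are_pure(self):
        C = ConfusionMatrix(tn=50, fn=0, fp=0, tp=30)
        assert variance_oa(C, AreaWeights(0.6, 0.4)) == 0.0

    def test_hand_reimplementation(self):
        # independent spellings of the printed estimators
        W = W_EX.as_array()
        c = C_EX.as_array()
        rows = c.sum(axis=1)
        P = np.array([c[0, 0] / rows[0], c[1, 1] / rows[1]])
        v_oa = sum(W[i] ** 2 * P[i] * (1 - P[i]) / (rows[i] - 1) for i in (0, 1))
        assert variance_oa(C_EX, W_EX) == pytest.approx(v_oa)

        v_ua = W[1] ** 2 * P[1] * (1 - P[1]) / (rows[1] - 1)
        assert variance_ua(C_EX, W_EX, 1) == pytest.approx(v_ua)
        assert variance_ua(C_EX, W_EX, 1, mode="standard") == pytest.approx(v_ua / W[1] ** 2)

        n = 10_000
        A = MappedAreaSummary(n_neg=7000, n_pos=3000)
        a = A.as_array()
        n_hat = (a[0] / rows[0]) * c[0, 1] + (a[1] / rows[1]) * c[1, 1]
        R = (W[1] * c[1, 1] / rows[1]) / (W[0] * c[0, 1] / rows[0] + W[1] * c[1, 1] / rows[1])
        term1 = a[1] ** 2 * (1 - R) ** 2 * P[1] * (1 - P[1]) / (rows[1] - 1)
        q = c[0, 1] / rows[0]
        term2 = R ** 2 * a[0] ** 2 * q * (1 - q) / (rows[0] - 1)
        assert variance_pa(C_EX, W_EX, A, 1) == pytest.approx((term1 + term2) / n_hat ** 2)

    def test_single_sample_row_reports_zero_se(self):
        C = ConfusionMatrix(tn=10, fn=2, fp=1, tp=0)
        assert variance_oa(C, AreaWeights(0.9, 0.1)) == 0.0


class TestF1:
    def test_symmetric_no_error(self):
        est = f1_with_error(MetricEstimate(0.5, 0.0), MetricEstimate(0.5, 0.0))
        assert (est.value, est.se) == (0.5, 0.0)

    def test_hand_propagation(self):
        est = f1_with_error(MetricEstimate(0.8, 0.05), MetricEstimate(0.6, 0.04))
        assert est.value == pytest.approx(0.685714, abs=1e-6)
        assert est.se == pytest.approx(0.132653, abs=1e-6)

    def test_degenerate_zero(self):
        est = f1_with_error(MetricEstimate(0.0, 0.0), MetricEstimate(0.0, 0.0))
        assert (est.value, est.se) == (0.0, 0.0)

    @given(
        p=st.floats(0, 1), r=st.floats(0, 1),
        dp=st.floats(0, 0.2), dr=st.floats(0, 0.2),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_symmetry_property(self, p, r, dp, dr):
        a = f1_with_error(MetricEstimate(p, dp), MetricEstimate(r, dr))
        b = f1_with_error(MetricEstimate(r, dr), MetricEstimate(p, dp))
        assert a.value == pytest.approx(b.value, abs=1e-12)
        assert a.se == pytest.approx(b.se, abs=1e-12)


@st.composite
def confusion_and_weights(draw):
    counts = [draw(st.integers(0, 200)) for _ in range(4)]
    C = ConfusionMatrix(*counts)
    rows = C.row_sums
    if rows.sum() == 0:
        C = ConfusionMatrix(1, 0, 0, 1)
        rows = C.row_sums
    if rows[0] == 0:
        w = AreaWeights(0.0, 1.0)
    elif rows[1] == 0:
        w = AreaWeights(1.0, 0.0)
    else:
        f = draw(st.floats(0.01, 0.99))
        w = AreaWeights(1 - f, f)
    return C, w


class TestInvariants:
    @given(confusion_and_weights())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_population_matrix_conservation(self, cw):
        C, W = cw
        E = population_matrix(C, W)
        assert E.p.sum() == pytest.approx(1.0, abs=1e-12)
        np.testing.assert_allclose(E.row_sums, W.as_array(), atol=1e-12)

    @given(confusion_and_weights())
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_metrics_bounded_and_ses_non_negative(self, cw):
        C, W = cw
        E = population_matrix(C, W)
        for v in (overall_accuracy(E), users_accuracy(E, 1), producers_accuracy(E, 1)):
            assert -1e-12 <= v <= 1 + 1e-12
        for var in (variance_oa(C, W), variance_ua(C, W, 1)):
            assert var >= 0

    def test_reduction_to_plain_confusion_metrics(self):
        # W equal to sample row shares: population metrics = naive metrics
        C = ConfusionMatrix(40, 10, 5, 45)
        W = AreaWeights(50 / 100, 50 / 100)
        E = population_matrix(C, W)
        assert overall_accuracy(E) == pytest.approx((40 + 45) / 100)
        assert users_accuracy(E, 1) == pytest.approx(45 / 50)
        assert producers_accuracy(E, 1) == pytest.approx(45 / 55)


class TestEvaluateMap:
    def test_mali_end_to_end(self, mali_fixture):
        cropmap, dataset = mali_fixture
        ev = evaluate_map(cropmap, dataset)
        assert ev.oa.rounded() == (0.98, 0.01)
        assert ev.ua_crop.rounded() == (0.0, 0.0)
        assert ev.pa_crop.rounded() == (0.0, 0.0)
        assert ev.f1_crop.rounded() == (0.0, 0.0)

    def test_perfect_map_scores_one_everywhere(self):
        rng = np.random.default_rng(8)
        m = make_map(rng.integers(0, 2, (12, 12)))
        from cropmapeval import ReferenceDataset, ReferencePoint
        cx, cy = m.grid.cell_centers()
        pts = tuple(
            ReferencePoint(id=str(i), lon=float(x), lat=float(y),
                           interpreter_labels=(int(v), int(v)), final_label=int(v))
            for i, (x, y, v) in enumerate(zip(cx.ravel(), cy.ravel(), m.values.ravel()))
        )
        ev = evaluate_map(m, ReferenceDataset("r", 2019, pts))
        for est in ev.metrics().values():
            assert est.rounded() == (1.0, 0.0)
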