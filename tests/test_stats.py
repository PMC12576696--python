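"""Detector scoring and group statistics against independent oracles."""

import numpy as np
import pytest
from scipy import stats as sps

from qbrm.detect import BoundingBox, Detection
from qbrm.stats import (
    density_correlation,
    detection_metrics,
    match_detections,
    one_way_anova,
    tukey_hsd,
)


def grid_boxes(n, size=4.0, pitch=20.0):
    cols = int(np.ceil(np.sqrt(n)))
    return [
        BoundingBox((i % cols) * pitch, (i // cols) * pitch, size, size)
        for i in range(n)
    ]


class TestMatching:
    def test_identical_lists_fully_matched(self):
        boxes = grid_boxes(5)
        m = match_detections([Detection(b, 0.9) for b in boxes], boxes, 0.5)
        assert len(m.pairs) == 5
        assert m.unmatched_pred == [] and m.unmatched_gt == []

    def test_disjoint_lists_no_pairs(self):
        m = match_detections(grid_boxes(3), [BoundingBox(500, 500, 4, 4)], 0.3)
        assert m.pairs == []
        assert len(m.unmatched_pred) == 3 and m.unmatched_gt == [0]

    def test_greedy_order_matches_exhaustive_oracle(self):
        # 3 predictions vs 2 references with a known IoU matrix
        gt = [BoundingBox(0, 0, 10, 10), BoundingBox(30, 0, 10, 10)]
        pred = [
            Detection(BoundingBox(2, 0, 10, 10), 0.7),   # iou .667 with gt0
            Detection(BoundingBox(0, 1, 10, 10), 0.9),   # iou .818 with gt0
            Detection(BoundingBox(33, 0, 10, 10), 0.8),  # iou .538 with gt1
        ]
        m = match_detections(pred, gt, 0.3)
        # confidence order 1, 2, 0: pred1 claims gt0, pred2 claims gt1,
        # pred0's only candidate is taken
        assert sorted(p[:2] for p in m.pairs) == [(1, 0), (2, 1)]
        assert m.unmatched_pred == [0]

    def test_match_is_one_to_one(self):
        gt = [BoundingBox(0, 0, 10, 10)]
        pred = [Detection(BoundingBox(0, 0, 10, 10), c) for c in (0.9, 0.8, 0.7)]
        m = match_detections(pred, gt, 0.3)
        assert len(m.pairs) == 1
        assert len(m.unmatched_pred) == 2


class TestMetrics:
    def test_count_arithmetic(self):
        gt = grid_boxes(8)
        pred = [Detection(b, 0.9) for b in gt[:6]] + [
            Detection(BoundingBox(500, 500 + 30 * i, 4, 4), 0.5) for i in range(1)
        ]
        rep = detection_metrics(match_detections(pred, gt, 0.5))
        assert (rep.tp, rep.fp, rep.fn) == (6, 1, 2)
        assert rep.sensitivity == pytest.approx(0.75)
        assert rep.ppv == pytest.approx(6 / 7)

    def test_perfect_detector(self):
        gt = grid_boxes(10)
        rep = detection_metrics(match_detections([Detection(b, 1.0) for b in gt], gt, 0.5))
        assert rep.sensitivity == 1.0 and rep.ppv == 1.0 and rep.fp_fraction == 0.0

    def test_identities_hold(self):
        rng = np.random.default_rng(0)
        gt = grid_boxes(30)
        pred = [Detection(b, float(rng.uniform(0.3, 1))) for b in gt if rng.uniform() < 0.7]
        pred += [Detection(BoundingBox(900 + 30 * i, 0, 4, 4), 0.4) for i in range(5)]
        m = match_detections(pred, gt, 0.5)
        rep = detection_metrics(m, evaluated_area_mm2=2.0)
        assert rep.tp + rep.fn == len(gt)
        assert rep.tp + rep.fp == len(pred)
        assert rep.ppv + rep.fp_fraction == pytest.approx(1.0)
        assert rep.fp_per_mm2 == pytest.approx(rep.fp / 2.0)

    def test_undefined_rates_flagged_none(self):
        rep = detection_metrics(match_detections([], grid_boxes(3), 0.5))
        assert rep.ppv is None and rep.fp_fraction is None
        rep2 = detection_metrics(match_detections([], [], 0.5))
        assert rep2.sensitivity is None

    def test_stochastic_corrupter_recovers_rates(self):
        # drop ground truth at p=0.25 and inject false boxes at 12% of the
        # output: estimates must land within 3 s.e. of 0.75 / 0.88
        rng = np.random.default_rng(7)
        n = 600
        gt = grid_boxes(n, pitch=12.0)
        kept = [b for b in gt if rng.uniform() >= 0.25]
        n_fp = int(round(len(kept) * 0.12 / 0.88))
        fps = [BoundingBox(10000 + 12 * i, 0, 4, 4) for i in range(n_fp)]
        pred = [Detection(b, 0.9) for b in kept + fps]
        rep = detection_metrics(match_detections(pred, gt, 0.5))
        se_sens = np.sqrt(0.75 * 0.25 / n)
        assert abs(rep.sensitivity - 0.75) < 3 * se_sens
        se_ppv = np.sqrt(0.88 * 0.12 / len(pred))
        assert abs(rep.ppv - 0.88) < 3 * se_ppv


class TestDensityCorrelation:
    def test_identity_line(self):
        x = [1.0, 2.0, 3.0, 4.0]
        slope, intercept, r2 = density_correlation(x, x)
        assert (slope, intercept, r2) == pytest.approx((1.0, 0.0, 1.0))

    def test_affine_line(self):
        x = np.array([0.0, 1.0, 2.0, 5.0])
        slope, intercept, r2 = density_correlation(2 * x + 1, x)
        assert (slope, intercept, r2) == pytest.approx((2.0, 1.0, 1.0))

    def test_matches_normal_equations_oracle(self):
        x = np.array([1.2, 3.4, 2.2, 5.1, 4.4, 0.7, 6.3, 2.9, 3.8, 5.6])
        y = np.array([2.1, 5.9, 4.4, 9.8, 8.1, 1.9, 12.2, 5.2, 7.7, 10.4])
        slope, intercept, r2 = density_correlation(y, x)
        xm = np.column_stack([np.ones_like(x), x])
        beta = np.linalg.solve(xm.T @ xm, xm.T @ y)
        resid = y - xm @ beta
        r2_oracle = 1.0 - resid @ resid / np.sum((y - y.mean()) ** 2)
        assert intercept == pytest.approx(beta[0], abs=1e-10)
        assert slope == pytest.approx(beta[1], abs=1e-10)
        assert r2 == pytest.approx(r2_oracle, abs=1e-10)

    def test_zero_reference_variance_flagged(self):
        with pytest.raises(ValueError, match="zero variance"):
            density_correlation([1.0, 2.0, 3.0], [5.0, 5.0, 5.0])


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = {"a": [1.0, 2.0, 3.0], "b": [1.0, 2.0, 3.0]}
        res = one_way_anova(g)
        assert res.F == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_two_group_f_equals_t_squared(self):
        a = [3.1, 4.5, 2.8, 5.0, 3.9]
        b = [6.2, 5.8, 7.1, 6.6]
        res = one_way_anova({"a": a, "b": b})
        t = sps.ttest_ind(a, b, equal_var=True)
        assert res.F == pytest.approx(t.statistic**2, rel=1e-12)
        assert res.p == pytest.approx(t.pvalue, rel=1e-12)

    def test_matches_scipy_f_oneway_oracle(self):
        groups = {
            "ctl": [6.9, 5.4, 5.8, 4.6, 4.0],
            "t1": [8.3, 6.8, 7.8, 9.2, 6.5],
            "t2": [8.0, 10.5, 8.1, 6.9, 9.3],
        }
        res = one_way_anova(groups)
        oracle = sps.f_oneway(*groups.values())
        assert res.F == pytest.approx(oracle.statistic, abs=1e-10)
        assert res.p == pytest.approx(oracle.pvalue, abs=1e-10)
        assert (res.df_between, res.df_within) == (2, 12)

    def test_invariance_to_shift_and_scale(self):
        rng = np.random.default_rng(3)
        groups = {k: rng.normal(i, 1, 6).tolist() for i, k in enumerate("abc")}
        base = one_way_anova(groups).F
        shifted = one_way_anova({k: [v + 100 for v in g] for k, g in groups.items()}).F
        scaled = one_way_anova({k: [v * 7 for v in g] for k, g in groups.items()}).F
        assert shifted == pytest.approx(base, rel=1e-9)
        assert scaled == pytest.approx(base, rel=1e-9)

    def test_too_few_groups_or_observations_rejected(self):
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0, 2.0]})
        with pytest.raises(ValueError):
            one_way_anova({"a": [1.0, 2.0], "b": [3.0]})


class TestTukey:
    def test_identical_groups_nothing_significant(self):
        g = [1.0, 2.0, 3.0, 2.5]
        table = tukey_hsd({"a": g, "b": list(g), "c": list(g)}, alpha=0.05)
        assert (table["p_adj"] > 0.99).all()
        assert not table["significant"].any()

    def test_matches_scipy_studentized_range_oracle(self):
        groups = {
            "a": [24.5, 23.5, 26.4, 27.1, 29.9],
            "b": [28.4, 34.2, 29.5, 32.2, 30.1],
            "c": [26.1, 28.3, 24.3, 26.2, 27.8],
        }
        table = tukey_hsd(groups, alpha=0.05)
        oracle = sps.tukey_hsd(*groups.values())
        labels = list(groups)
        for _, row in table.iterrows():
            i, j = labels.index(row.group_a), labels.index(row.group_b)
            assert row.p_adj == pytest.approx(oracle.pvalue[i, j], abs=1e-6)

    def test_unequal_n_tukey_kramer_matches_scipy(self):
        groups = {
            "a": [1.1, 2.3, 1.9, 2.8],
            "b": [4.5, 5.1, 4.2],
            "c": [1.5, 2.0, 2.6, 1.2, 2.2],
        }
        table = tukey_hsd(groups)
        oracle = sps.tukey_hsd(*groups.values())
        labels = list(groups)
        for _, row in table.iterrows():
            i, j = labels.index(row.group_a), labels.index(row.group_b)
            assert row.p_adj == pytest.approx(oracle.pvalue[i, j], abs=1e-6)

    def test_outlying_group_drives_exactly_its_two_pairs(self):
        rng = np.random.default_rng(1)
        groups = {
            "lo1": rng.normal(5, 1, 6).tolist(),
            "lo2": rng.normal(5.3, 1, 6).tolist(),
            "hi": rng.normal(40, 1, 6).tolist(),
        }
        table = tukey_hsd(groups, alpha=0.01)
        sig = table[table["significant"]]
        assert len(sig) == 2
        assert all("hi" in (r.group_a, r.group_b) for _, r in sig.iterrows())
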