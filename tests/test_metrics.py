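"""Metric-suite tests with hand-computed and library cross-check oracles."""

import numpy as np
import pytest

from periostage.metrics import (
    RaterTable,
    average_precision,
    classification_report,
    detection_pr_map,
    error_metrics,
    icc_2_1,
    roc_auc,
    seg_metrics,
)


class TestSegMetrics:
    def test_identical_masks_all_one(self, rng):
        m = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        s = seg_metrics(m, m)
        assert (s.accuracy, s.precision, s.recall, s.f1, s.iou, s.dice) == (
            1.0, 1.0, 1.0, 1.0, 1.0, 1.0,
        )

    def test_complement_masks_zero_overlap(self, rng):
        t = (rng.random((32, 32)) > 0.5).astype(np.uint8)
        s = seg_metrics(1 - t, t)
        assert s.precision == s.recall == s.iou == s.dice == 0.0
        assert s.accuracy == 0.0

    def test_offset_squares_pixel_count_oracle(self):
        truth = np.zeros((20, 20), dtype=np.uint8)
        pred = np.zeros((20, 20), dtype=np.uint8)
        truth[5:11, 5:11] = 1
        pred[5:11, 7:13] = 1  # 6x6 squares offset by 2 px: overlap 6x4=24
        s = seg_metrics(pred, truth)
        assert s.iou == pytest.approx(24 / 48)
        assert s.dice == pytest.approx(2 / 3)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError):
            seg_metrics(np.zeros((4, 4)), np.zeros((4, 5)))


class TestRocAuc:
    def test_perfect_separation(self):
        assert roc_auc([0.1, 0.2, 0.8, 0.9], [0, 0, 1, 1]) == 1.0

    def test_constant_scores_are_chance(self):
        assert roc_auc([0.5] * 6, [0, 1, 0, 1, 0, 1]) == 0.5

    def test_hand_counted_pairs(self):
        assert roc_auc([0.1, 0.4, 0.35, 0.8], [0, 0, 1, 1]) == pytest.approx(0.75)

    def test_single_class_rejected(self):
        with pytest.raises(ValueError):
            roc_auc([0.1, 0.9], [1, 1])

    def test_matches_sklearn_on_random_instances(self, rng):
        from sklearn.metrics import roc_auc_score

        for _ in range(20):
            n = int(rng.integers(5, 60))
            scores = rng.choice([0.1, 0.3, 0.5, 0.7, 0.9], n)  # heavy ties
            labels = rng.integers(0, 2, n)
            if labels.min() == labels.max():
                continue
            assert roc_auc(scores, labels) == pytest.approx(
                roc_auc_score(labels, scores), abs=1e-12
            )


class TestErrorMetrics:
    def test_identity(self):
        assert error_metrics([1.0, 2.0], [1.0, 2.0]) == (0.0, 0.0)

    def test_symmetric_errors(self):
        mae, rmse = error_metrics([3.0, -3.0], [0.0, 0.0])
        assert (mae, rmse) == (3.0, 3.0)

    def test_hand_arithmetic(self):
        mae, rmse = error_metrics([1.0, 2.0, 3.0], [0.0, 0.0, 0.0])
        assert mae == pytest.approx(2.0)
        assert rmse == pytest.approx(np.sqrt(14 / 3))
        assert round(rmse, 4) == 2.1602


class TestIcc:
    def _table(self, v):
        v = np.asarray(v, dtype=float)
        return RaterTable(v, tuple(f"r{i}" for i in range(v.shape[1])))

    def test_identical_raters_exactly_one(self):
        v = np.tile(np.array([[3.0], [5.0], [9.0], [1.0], [7.0]]), (1, 3))
        assert icc_2_1(self._table(v)).icc == 1.0

    def test_constant_offset_penalized_vs_consistency(self):
        """ICC(2,1) punishes a systematic offset; the consistency ICC does
        not.  Cross-checked against a direct ANOVA decomposition."""
        subjects = np.arange(1.0, 7.0)
        v = np.column_stack([subjects, subjects + 10.0])
        res = icc_2_1(self._table(v))
        assert res.icc < 1.0
        # consistency ICC via the same ANOVA sums of squares: (MSR-MSE)/(MSR+(k-1)MSE)
        n, k = v.shape
        grand = v.mean()
        msr = k * ((v.mean(1) - grand) ** 2).sum() / (n - 1)
        msc = n * ((v.mean(0) - grand) ** 2).sum() / (k - 1)
        mse = (((v - grand) ** 2).sum() - (n - 1) * msr - (k - 1) * msc) / ((n - 1) * (k - 1))
        icc_consistency = (msr - mse) / (msr + (k - 1) * mse)
        assert res.icc < icc_consistency

    def test_independent_raters_near_zero(self, rng):
        v = rng.normal(size=(200, 3))
        assert abs(icc_2_1(self._table(v)).icc) < 0.1

    def test_shift_all_cells_invariant_but_one_rater_not(self, rng):
        v = rng.normal(0, 1, (30, 3)) + rng.normal(0, 2, (30, 1))
        base = icc_2_1(self._table(v)).icc
        assert icc_2_1(self._table(v + 7.3)).icc == pytest.approx(base, abs=1e-9)
        shifted = v.copy()
        shifted[:, 0] += 5.0
        assert icc_2_1(self._table(shifted)).icc != pytest.approx(base, abs=1e-3)

    def test_matches_pingouin(self, rng):
        import pandas as pd
        import pingouin as pg

        for _ in range(10):
            n, k = int(rng.integers(6, 30)), int(rng.integers(2, 5))
            v = rng.normal(0, 2, (n, 1)) + rng.normal(0, 0.5, (1, k)) + rng.normal(0, 1, (n, k))
            res = icc_2_1(self._table(v))
            df = pd.DataFrame({
                "s": np.repeat(np.arange(n), k),
                "r": np.tile(np.arange(k), n),
                "v": v.ravel(),
            })
            row = pg.intraclass_corr(df, targets="s", raters="r", ratings="v"
                                     ).set_index("Type").loc["ICC(A,1)"]
            assert res.icc == pytest.approx(row["ICC"], abs=1e-10)
            assert res.f_value == pytest.approx(row["F"], rel=1e-8)
            assert res.ci95[0] == pytest.approx(row["CI95"][0], abs=0.015)
            assert res.ci95[1] == pytest.approx(row["CI95"][1], abs=0.015)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            res = icc_2_1(self._table(np.full((5, 3), 2.0)))
        assert res.icc == 1.0

    def test_table_validation(self):
        with pytest.raises(ValueError):
            RaterTable(np.zeros((1, 3)), ("a", "b", "c"))
        with pytest.raises(ValueError):
            RaterTable(np.array([[1.0, np.nan], [2.0, 3.0]]), ("a", "b"))


class TestClassificationReport:
    def test_perfect_predictions(self):
        rep = classification_report(["A", "B", "A"], ["A", "B", "A"])
        assert rep["overall"]["accuracy"] == 1.0
        assert all(m.f1 == 1.0 for m in rep["per_class"].values())

    def test_high_precision_class_arithmetic(self):
        """A class predicted only when correct: precision 1, F1 from recall."""
        truth = ["III/IV"] * 181
        pred = ["III/IV"] * 162 + ["I"] * 19
        rep = classification_report(truth, pred, classes=["I", "II", "III/IV"])
        m = rep["per_class"]["III/IV"]
        assert m.precision == 1.0
        assert round(m.recall, 4) == 0.8950
        assert round(m.f1, 4) == 0.9446
        assert m.accuracy == m.recall

    def test_never_predicted_class_all_zero(self):
        rep = classification_report(["I", "I", "II"], ["II", "II", "II"])
        m = rep["per_class"]["I"]
        assert (m.precision, m.recall, m.f1) == (0.0, 0.0, 0.0)
        assert m.support == 2

    def test_unseen_predicted_class_warns_and_counts(self):
        with pytest.warns(UserWarning):
            rep = classification_report(["A", "A"], ["A", "X"], classes=["A"])
        assert "X" in rep["per_class"]

    def test_overall_weighted_by_support(self):
        truth = ["A"] * 8 + ["B"] * 2
        pred = ["A"] * 8 + ["A"] * 2
        rep = classification_report(truth, pred)
        assert rep["overall"]["accuracy"] == 0.8
        # weighted precision: A: 8/10 weighted 0.8, B: 0 weighted 0.2
        assert rep["overall"]["precision"] == pytest.approx(0.8 * 0.8)


class TestDetectionAp:
    def _d(self, x, y, conf):
        return ((x, y, 10.0, 10.0), conf)

    def test_perfect_detections(self):
        truths = [(0.0, 0.0, 10.0, 10.0), (50.0, 50.0, 10.0, 10.0)]
        dets = [(t, 0.9) for t in truths]
        res = detection_pr_map(dets, truths)
        assert res["map"] == 1.0
        assert all(v["precision"] == v["recall"] == 1.0
                   for v in res["per_threshold"].values())

    def test_no_detections(self):
        ap, p, r = average_precision([], [(0, 0, 10, 10)], 0.5)
        assert (ap, r) == (0.0, 0.0)

    def test_toy_layout_matches_brute_force_pr(self):
        """5 detections / 4 truths: AP equals the step-by-step PR curve."""
        truths = [(0, 0, 10, 10), (20, 0, 10, 10), (40, 0, 10, 10), (60, 0, 10, 10)]
        dets = [
            self._d(0, 0, 0.95),   # TP
            self._d(100, 0, 0.9),  # FP
            self._d(20, 0, 0.8),   # TP
            self._d(40, 8, 0.7),   # IoU = 2/18 < 0.5 -> FP
            self._d(60, 1, 0.6),   # IoU = 9/11 -> TP
        ]
        ap, _, recall = average_precision(dets, truths, 0.5)
        # brute force: flags [1,0,1,0,1]; precision at TP ranks: 1/1, 2/3, 3/5
        # monotone envelope: 1, 2/3, 3/5; AP = (1 + 2/3 + 3/5)/4
        assert ap == pytest.approx((1 + 2 / 3 + 3 / 5) / 4)
        assert recall == pytest.approx(3 / 4)


class TestMetricIdentities:
    def test_rmse_ge_mae_and_dice_ge_iou(self, rng):
        for _ in range(200):
            a = rng.normal(size=rng.integers(1, 20))
            b = rng.normal(size=a.size)
            mae, rmse = error_metrics(a, b)
            assert rmse >= mae - 1e-12
            m1 = (rng.random((8, 8)) > 0.5).astype(np.uint8)
            m2 = (rng.random((8, 8)) > 0.5).astype(np.uint8)
            s = seg_metrics(m1, m2)
            assert s.dice >= s.iou - 1e-12
            if s.iou not in (0.0, 1.0):
                assert s.dice > s.iou
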