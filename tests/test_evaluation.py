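import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from chisel.errors import ParameterError, ValidationError
from chisel.evaluation import (
    EvalCounts,
    classwise_metrics,
    detection_metrics,
    match_objects,
    pixel_metrics,
    sweep_parameter,
)


def markers(*rows):
    return pd.DataFrame(rows, columns=["x", "y", "class"])


def one_object(shape=(20, 20), box=(5, 5, 10, 10)):
    lab = np.zeros(shape, dtype=np.int32)
    r0, c0, r1, c1 = box
    lab[r0:r1, c0:c1] = 1
    return lab


class TestMatchObjects:
    def test_marker_inside_object_is_tp(self):
        c = match_objects(one_object(), markers((7, 7, "positive")))
        assert (c.TP, c.FP, c.FN) == (1, 0, 0)

    def test_surplus_marker_in_same_object_is_fn(self):
        c = match_objects(one_object(), markers((6, 6, "positive"), (8, 8, "negative")))
        assert (c.TP, c.FP, c.FN) == (1, 0, 1)

    def test_unmatched_object_and_marker(self):
        c = match_objects(one_object(), markers((15, 15, "positive")))
        assert (c.TP, c.FP, c.FN) == (0, 1, 1)

    def test_marker_outside_extent_rejected(self):
        with pytest.raises(ValidationError):
            match_objects(one_object(), markers((50, 2, "positive")))

    def test_count_identities(self, rng):
        # TP + FN = markers, TP + FP = objects, on random configurations
        for _ in range(20):
            lab = np.zeros((30, 30), dtype=np.int32)
            n_obj = rng.integers(1, 5)
            for i in range(n_obj):
                r, c = rng.integers(0, 24, 2)
                lab[r : r + 5, c : c + 5] = i + 1
            lab = np.unique(lab, return_inverse=True)[1].reshape(lab.shape)
            n_obj = lab.max()
            mks = markers(
                *[(int(x), int(y), "positive")
                  for x, y in rng.integers(0, 30, (rng.integers(0, 6), 2))]
            ) if rng.random() > 0.1 else markers()
            c = match_objects(lab, mks)
            assert c.TP + c.FN == len(mks)
            assert c.TP + c.FP == n_obj


class TestDetectionMetrics:
    def test_hand_counted_fixture(self):
        ppv, tpr, f1 = detection_metrics(EvalCounts(TP=8, FP=2, FN=2))
        assert (ppv, tpr, f1) == (0.8, 0.8, pytest.approx(0.8))

    def test_degenerate_zero_convention(self):
        assert detection_metrics(EvalCounts(TP=0, FP=0, FN=5)) == (0.0, 0.0, 0.0)
        assert detection_metrics(EvalCounts(TP=0, FP=0, FN=0)) == (0.0, 0.0, 0.0)

    def test_harmonic_mean_of_published_style_rates(self):
        # pooled harmonic mean of TPR .816 / PPV .707; macro-averaged
        # per-image scores differ from this, hence the aggregation switch
        ppv, tpr = 0.707, 0.816
        f1 = 2 * ppv * tpr / (ppv + tpr)
        assert f1 == pytest.approx(0.7576, abs=1e-4)

    @given(tp=st.integers(0, 50), fp=st.integers(0, 50), fn=st.integers(0, 50))
    @settings(max_examples=100, derandomize=True, deadline=None)
    def test_f1_harmonic_bounds(self, tp, fp, fn):
        ppv, tpr, f1 = detection_metrics(EvalCounts(TP=tp, FP=fp, FN=fn))
        assert 0 <= f1 <= max(ppv, tpr) + 1e-12
        assert f1 <= (ppv + tpr) / 2 + 1e-12
        if ppv + tpr > 0:
            assert f1 >= min(ppv, tpr) * 2 * max(ppv, tpr) / (ppv + tpr) - 1e-12


class TestClasswiseMetrics:
    def test_agreeing_match_is_class_tp(self):
        m = classwise_metrics(one_object(), {1: "positive"}, markers((7, 7, "positive")))
        assert m["positive"] == (1.0, 1.0, 1.0)

    def test_mismatched_classes_split_into_fp_and_fn(self):
        lab = one_object()
        counts = classwise_metrics(lab, {1: "positive"}, markers((7, 7, "negative")))
        ppv_pos, tpr_pos, _ = counts["positive"]
        ppv_neg, tpr_neg, _ = counts["negative"]
        assert ppv_pos == 0.0  # predicted positive was an FP
        assert tpr_neg == 0.0  # the negative marker went unfound

    def test_no_objects_zero_recall_both_classes(self):
        lab = np.zeros((20, 20), dtype=np.int32)
        m = classwise_metrics(lab, {}, markers((3, 3, "positive"), (5, 5, "negative")))
        assert m["positive"][1] == 0.0 and m["negative"][1] == 0.0

    def test_unspecified_marker_class_rejected(self):
        with pytest.raises(ValidationError):
            classwise_metrics(one_object(), {1: "positive"}, markers((7, 7, "unspecified")))


class TestPixelMetrics:
    def test_perfect_prediction(self):
        gt = np.zeros((10, 10), bool)
        gt[2:5, 2:5] = True
        assert pixel_metrics(gt, gt) == (1.0, 1.0, 1.0)

    def test_disjoint_masks_zero(self):
        a = np.zeros((10, 10), bool)
        b = np.zeros((10, 10), bool)
        a[0, 0] = True
        b[5, 5] = True
        assert pixel_metrics(a, b) == (0.0, 0.0, 0.0)

    def test_half_coverage(self):
        gt = np.zeros((10, 10), bool)
        gt[0, :8] = True
        pred = np.zeros((10, 10), bool)
        pred[0, :4] = True
        ppv, tpr, f1 = pixel_metrics(pred, gt)
        assert (ppv, tpr) == (1.0, 0.5) and f1 == pytest.approx(2 / 3)

    def test_region_restriction(self):
        gt = np.zeros((10, 10), bool)
        gt[:, :5] = True
        pred = np.ones((10, 10), bool)
        region = np.zeros((10, 10), bool)
        region[:, :5] = True
        assert pixel_metrics(pred, gt, region) == (1.0, 1.0, 1.0)

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValidationError):
            pixel_metrics(np.zeros((3, 3), bool), np.zeros((4, 4), bool))


class TestSweep:
    @pytest.fixture(scope="class")
    def sweep_data(self):
        from chisel.synthetic import generate_scene, preset_spec

        imgs, mks = [], []
        for seed in (40, 41):
            sc = generate_scene(
                preset_spec(
                    "iispv", height=300, width=300, n_nuclei=12,
                    cluster_fraction=0.0, seed=seed,
                    positive_hsv=(0.07, 0.25, 0.62),
                    negative_hsv=(0.60, 0.25, 0.60),
                    noise_sd=0.02, bg_texture_sd=0.03,
                )
            )
            imgs.append(sc.image)
            mks.append(sc.gt_markers)
        return imgs, mks

    def _cfg(self):
        from chisel.config import PipelineConfig

        return PipelineConfig(roi_size=300, scheme="A", window=51, ac_iterations=0)

    def test_single_value_single_point(self, sweep_data):
        imgs, mks = sweep_data
        curve = sweep_parameter(imgs, mks, "threshold_t", [15.0], self._cfg())
        assert len(curve.values) == 1 and curve.best_value == 15.0

    def test_interior_optimum_under_low_contrast(self, sweep_data):
        imgs, mks = sweep_data
        curve = sweep_parameter(
            imgs, mks, "threshold_t", [5, 10, 15, 20, 25], self._cfg()
        )
        assert curve.best_value in (10, 15, 20)
        assert max(curve.f1) > curve.f1[0] or max(curve.f1) > curve.f1[-1]

    def test_sweep_deterministic(self, sweep_data):
        imgs, mks = sweep_data
        c1 = sweep_parameter(imgs, mks, "threshold_t", [10, 20], self._cfg())
        c2 = sweep_parameter(imgs, mks, "threshold_t", [10, 20], self._cfg())
        assert c1.f1 == c2.f1

    def test_empty_value_list_rejected(self, sweep_data):
        imgs, mks = sweep_data
        with pytest.raises(ParameterError):
            sweep_parameter(imgs, mks, "threshold_t", [], self._cfg())
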