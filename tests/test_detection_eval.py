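"""Detector and evaluation-metric tests, including exhaustive small-case oracles."""

import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st

from ecti.afm_io import BoundingBox, write_detections_yolo
from ecti.detection_eval import (AP5095_THRESHOLDS, BlobParams, ap50_95,
                                 average_precision, detect_blobs,
                                 f1_confidence_curve, iou,
                                 load_external_detections, match_detections, nms)
from ecti.exceptions import FormatError, ParameterError, UndefinedMetricError
from ecti.synthetic_data import SyntheticSpec, generate_corneocyte_image
from ecti.enhancement import enhance_pipeline

from conftest import make_detection_set


class TestIoU:
    def test_identical_boxes(self):
        b = BoundingBox(3, 4, 10, 12)
        assert iou(b, b) == 1.0

    def test_disjoint_boxes(self):
        assert iou(BoundingBox(0, 0, 5, 5), BoundingBox(10, 10, 15, 15)) == 0.0

    def test_half_overlap_arithmetic(self):
        assert iou(BoundingBox(0, 0, 10, 10), BoundingBox(5, 0, 15, 10)) == \
            pytest.approx(1 / 3)

    @given(st.integers(0, 2**32 - 1))
    def test_symmetric_and_bounded(self, seed):
        r = np.random.default_rng(seed)

        def random_box():
            x0, y0 = r.uniform(0, 50, 2)
            w, h = r.uniform(1, 40, 2)
            return BoundingBox(x0, y0, x0 + w, y0 + h)

        a, b = random_box(), random_box()
        assert iou(a, b) == pytest.approx(iou(b, a))
        assert 0.0 <= iou(a, b) <= 1.0


def _nms_oracle(boxes, scores, iou_thresh):
    """Greedy suppression by definition, with the (score desc, y, x) tie rule."""
    remaining = list(range(len(boxes)))
    kept = []
    while remaining:
        def key(i):
            cx = 0.5 * (boxes[i][0] + boxes[i][2])
            cy = 0.5 * (boxes[i][1] + boxes[i][3])
            return (-scores[i], cy, cx)
        best = min(remaining, key=key)
        kept.append(best)
        remaining = [i for i in remaining if i == best or
                     iou(BoundingBox(*boxes[best]), BoundingBox(*boxes[i])) < iou_thresh]
        remaining.remove(best)
    return kept


class TestNMS:
    def test_duplicate_boxes_keep_highest_score(self):
        ds = make_detection_set([(0, 0, 10, 10), (0, 0, 10, 10)], scores=[0.9, 0.8])
        out = nms(ds, 0.5)
        assert len(out) == 1 and out.detections[0].score == 0.9

    def test_disjoint_boxes_unchanged(self):
        ds = make_detection_set([(0, 0, 10, 10), (50, 50, 60, 60)], scores=[0.5, 0.6])
        assert len(nms(ds, 0.5)) == 2

    def test_unscored_detections_rejected(self):
        ds = make_detection_set([(0, 0, 10, 10)])
        with pytest.raises(ParameterError):
            nms(ds, 0.5)

    @given(st.integers(0, 2**32 - 1))
    def test_matches_exhaustive_oracle(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 15))
        x0 = r.uniform(0, 80, n)
        y0 = r.uniform(0, 80, n)
        boxes = np.c_[x0, y0, x0 + r.uniform(5, 20, n), y0 + r.uniform(5, 20, n)]
        # quantized scores force ties, exercising the tie rule
        scores = r.integers(1, 5, n) / 5.0
        ds = make_detection_set(boxes, scores=scores, image_w=100, image_h=100)
        out = nms(ds, 0.3)
        expected = _nms_oracle(boxes.tolist(), scores.tolist(), 0.3)
        got_boxes = {(d.box.x_min, d.box.y_min) for d in out}
        exp_boxes = {(boxes[i][0], boxes[i][1]) for i in expected}
        assert got_boxes == exp_boxes


class TestMatching:
    def test_perfect_detector_all_tp(self):
        gts = make_detection_set([(0, 0, 10, 10), (20, 20, 30, 30)])
        dets = make_detection_set([(0, 0, 10, 10), (20, 20, 30, 30)],
                                  scores=[0.9, 0.8])
        ledger = match_detections(dets, gts, 0.5)
        assert ledger.n_tp == 2 and ledger.n_fp == 0 and ledger.n_fn == 0

    def test_double_detection_counts_one_tp_one_fp(self):
        gts = make_detection_set([(0, 0, 10, 10)])
        dets = make_detection_set([(0, 0, 10, 10), (1, 1, 11, 11)],
                                  scores=[0.9, 0.8])
        ledger = match_detections(dets, gts, 0.5)
        assert ledger.n_tp == 1 and ledger.n_fp == 1
        assert ledger.is_tp[0] and not ledger.is_tp[1]  # the 0.9 wins

    def test_no_detections_all_fn(self):
        gts = make_detection_set([(0, 0, 10, 10)] * 3)
        dets = make_detection_set([], scores=[])
        ledger = match_detections(dets, gts, 0.5)
        assert ledger.n_fn == 3


def _ap_trapezoid(ledger):
    """All-points AP: exact integral of the precision envelope over recall."""
    if len(ledger.det_scores) == 0:
        return 0.0
    tp = np.cumsum(ledger.is_tp)
    fp = np.cumsum(~ledger.is_tp)
    recall = np.concatenate([[0.0], tp / ledger.n_gt])
    precision = np.concatenate([[1.0], tp / (tp + fp)])
    env = np.maximum.accumulate(precision[::-1])[::-1]
    return float(np.sum((recall[1:] - recall[:-1]) * env[1:]))


class TestAveragePrecision:
    def test_perfect_detector_is_one(self):
        gts = make_detection_set([(0, 0, 10, 10), (30, 30, 40, 40)])
        dets = make_detection_set([(0, 0, 10, 10), (30, 30, 40, 40)],
                                  scores=[0.9, 0.8])
        assert average_precision(dets, gts, 0.5) == pytest.approx(1.0)

    def test_no_detections_is_zero(self):
        gts = make_detection_set([(0, 0, 10, 10)])
        assert average_precision(make_detection_set([], scores=[]), gts, 0.5) == 0.0

    def test_tp_before_fp_keeps_envelope_at_one(self):
        gts = make_detection_set([(0, 0, 10, 10)])
        dets = make_detection_set([(0, 0, 10, 10), (50, 50, 60, 60)],
                                  scores=[0.9, 0.8])
        assert average_precision(dets, gts, 0.5) == pytest.approx(1.0)

    def test_undefined_without_ground_truth(self):
        gts = make_detection_set([])
        dets = make_detection_set([(0, 0, 10, 10)], scores=[0.9])
        with pytest.raises(UndefinedMetricError):
            average_precision(dets, gts, 0.5)

    def test_step_function_closed_form(self):
        # 2 gts; one TP at high score, then one FP: envelope is 1 up to
        # recall 0.5 and 0 beyond -> 101-point AP = 51/101
        gts = make_detection_set([(0, 0, 10, 10), (30, 30, 40, 40)])
        dets = make_detection_set([(0, 0, 10, 10), (60, 60, 70, 70)],
                                  scores=[0.9, 0.8])
        assert average_precision(dets, gts, 0.5) == pytest.approx(51 / 101)

    @given(st.integers(0, 2**32 - 1))
    def test_close_to_trapezoid_oracle(self, seed):
        r = np.random.default_rng(seed)
        n_gt = int(r.integers(1, 15))
        gx = r.uniform(10, 400, n_gt)
        gy = r.uniform(10, 400, n_gt)
        gts = make_detection_set(np.c_[gx, gy, gx + 20, gy + 20])
        n_det = int(r.integers(1, 30))
        idx = r.integers(0, n_gt, n_det)
        jitter = r.uniform(-8, 8, (n_det, 2))
        dx = gx[idx] + jitter[:, 0]
        dy = gy[idx] + jitter[:, 1]
        dets = make_detection_set(np.c_[dx, dy, dx + 20, dy + 20],
                                  scores=r.uniform(0, 1, n_det))
        ledger = match_detections(dets, gts, 0.5)
        ap = average_precision(dets, gts, 0.5)
        assert abs(ap - _ap_trapezoid(ledger)) <= 0.02


class TestAp5095:
    def test_perfect_detector(self):
        gts = make_detection_set([(0, 0, 10, 10)])
        dets = make_detection_set([(0, 0, 10, 10)], scores=[0.9])
        res = ap50_95(dets, gts)
        assert res.ap50 == pytest.approx(1.0)
        assert res.ap50_95 == pytest.approx(1.0)

    def test_constructed_iou_passes_only_low_thresholds(self):
        # boxes shifted by 2.4 px have IoU = 76/124 ~ 0.61 at every gt:
        # AP=1 at thresholds up to 0.60, 0 above; 3 of 10 thresholds pass
        gts = make_detection_set([(i * 30, 0, i * 30 + 10, 10) for i in range(5)])
        dets = make_detection_set([(i * 30 + 2.4, 0, i * 30 + 12.4, 10) for i in range(5)],
                                  scores=[0.9] * 5)
        pair_iou = iou(gts.detections[0].box, dets.detections[0].box)
        assert 0.55 < pair_iou < 0.65
        res = ap50_95(dets, gts)
        assert res.ap50 == pytest.approx(1.0)
        n_passing = sum(1 for t in AP5095_THRESHOLDS if t <= pair_iou)
        assert res.ap50_95 == pytest.approx(n_passing / 10)

    @given(st.integers(0, 2**32 - 1))
    def test_ap5095_never_exceeds_ap50(self, seed):
        r = np.random.default_rng(seed)
        n = int(r.integers(1, 10))
        gx = r.uniform(10, 400, n)
        gts = make_detection_set(np.c_[gx, gx, gx + 15, gx + 15])
        dx = gx + r.uniform(-6, 6, n)
        dets = make_detection_set(np.c_[dx, dx, dx + 15, dx + 15],
                                  scores=r.uniform(0, 1, n))
        res = ap50_95(dets, gts)
        assert res.ap50_95 <= res.ap50 + 1e-12


class TestF1Curve:
    def test_perfect_detector_single_score(self):
        gts = make_detection_set([(0, 0, 10, 10)])
        dets = make_detection_set([(0, 0, 10, 10)], scores=[0.9])
        curve = f1_confidence_curve(dets, gts)
        assert curve.best_f1 == pytest.approx(1.0)
        assert curve.best_threshold == pytest.approx(0.9)

    def test_threshold_separates_high_tp_from_low_fp(self):
        gts = make_detection_set([(0, 0, 10, 10), (30, 30, 40, 40)])
        dets = make_detection_set(
            [(0, 0, 10, 10), (30, 30, 40, 40), (70, 70, 80, 80), (90, 90, 100, 100)],
            scores=[0.9, 0.8, 0.2, 0.1])
        curve = f1_confidence_curve(dets, gts)
        assert curve.best_f1 == pytest.approx(1.0)
        assert curve.best_threshold == pytest.approx(0.8)

    def test_f1_is_harmonic_mean_everywhere(self, rng):
        gts = make_detection_set([(i * 30, 0, i * 30 + 10, 10) for i in range(4)])
        boxes = [(i * 30 + 3, 0, i * 30 + 13, 10) for i in range(4)] + \
                [(300, 300, 310, 310)]
        dets = make_detection_set(boxes, scores=rng.uniform(0, 1, 5))
        curve = f1_confidence_curve(dets, gts)
        for p, r, f in zip(curve.precision, curve.recall, curve.f1):
            expected = 2 * p * r / (p + r) if p + r else 0.0
            assert f == pytest.approx(expected)

    def test_empty_detections_degenerate(self):
        gts = make_detection_set([(0, 0, 10, 10)])
        curve = f1_confidence_curve(make_detection_set([], scores=[]), gts)
        assert curve.best_f1 == 0.0

    def test_recall_monotone_in_descending_threshold(self, rng):
        gts = make_detection_set([(i * 40, 0, i * 40 + 10, 10) for i in range(5)])
        dets = make_detection_set([(i * 40 + 2, 0, i * 40 + 12, 10) for i in range(5)],
                                  scores=rng.uniform(0, 1, 5))
        curve = f1_confidence_curve(dets, gts)
        assert (np.diff(curve.recall) >= -1e-12).all()


class TestDetectBlobs:
    def test_all_zero_image_no_detections(self):
        assert len(detect_blobs(np.zeros((64, 64)), 39.0625)) == 0

    def test_noise_free_bumps_recovered_exactly(self):
        spec = SyntheticSpec(cno_density_per_um2=25 / 400.0, stripe_amp_nm=0,
                             n_ridges=0, occlusion_fraction=0,
                             background_roughness_nm=0, size_jitter=0,
                             min_cno_spacing_px=40, seed=7)
        img = generate_corneocyte_image(spec)
        assert len(img.ground_truth) == 25
        enhanced = enhance_pipeline(img.height_map)
        ds = detect_blobs(enhanced, spec.pixel_size_nm)
        assert len(ds) == 25
        from scipy.spatial import cKDTree
        dist, _ = cKDTree(ds.centroids()).query(img.ground_truth.centroids())
        assert dist.max() < 1.0

    def test_detections_scored_and_in_bounds(self):
        spec = SyntheticSpec(n_rows=256, n_cols=256, cno_density_per_um2=0.6, seed=3)
        img = generate_corneocyte_image(spec)
        ds = detect_blobs(enhance_pipeline(img.height_map), spec.pixel_size_nm)
        assert len(ds) > 0
        for d in ds:
            assert 0.0 <= d.score <= 1.0
            assert d.box.x_max <= 256 and d.box.y_max <= 256

    def test_rejects_nonpositive_pixel_size(self):
        with pytest.raises(ParameterError):
            detect_blobs(np.zeros((64, 64)), 0.0)


class TestExternalAdapter:
    def test_round_trip_equivalence(self, tmp_path, rng):
        gx = rng.uniform(50, 400, 12)
        gts = make_detection_set(np.c_[gx, gx, gx + 14, gx + 14])
        dx = gx + rng.uniform(-2, 2, 12)
        dets = make_detection_set(np.c_[dx, dx, dx + 14, dx + 14],
                                  scores=rng.uniform(0.2, 1.0, 12))
        path = write_detections_yolo(dets, tmp_path / "preds.txt")
        loaded = load_external_detections(path, 512, 512)
        assert loaded.source == "external"
        direct = average_precision(dets, gts, 0.5)
        via_file = average_precision(loaded, gts, 0.5)
        assert via_file == pytest.approx(direct, abs=1e-6)

    def test_missing_scores_rejected(self, tmp_path):
        p = tmp_path / "gt.txt"
        p.write_text("0 0.5 0.5 0.1 0.1\n")
        with pytest.raises(FormatError):
            load_external_detections(p, 512, 512)

    def test_evaluation_invariant_to_file_order(self, tmp_path, rng):
        gx = rng.uniform(50, 400, 10)
        gts = make_detection_set(np.c_[gx, gx, gx + 14, gx + 14])
        dx = gx + rng.uniform(-3, 3, 10)
        scores = rng.uniform(0, 1, 10)
        dets = make_detection_set(np.c_[dx, dx, dx + 14, dx + 14], scores=scores)
        perm = rng.permutation(10)
        shuffled = make_detection_set(np.c_[dx, dx, dx + 14, dx + 14][perm],
                                      scores=scores[perm])
        assert average_precision(dets, gts, 0.5) == \
            pytest.approx(average_precision(shuffled, gts, 0.5))
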