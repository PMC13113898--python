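"""IoU, NMS, precision/recall, AP/mAP and theoretical FPS."""

import numpy as np
import pytest

from edgebcs import (iou, nms, pr_counts, average_precision, map_score,
                     theoretical_fps, Detection, GroundTruth,
                     evaluate_detections)
from edgebcs.metrics import class_pr_curve


def det(box, cls=0, conf=0.9, img=0):
    return Detection(box, cls, conf, img)


def gt(box, cls=0, img=0):
    return GroundTruth(box, cls, img)


class TestIoU:
    def test_identical(self):
        assert iou((0, 0, 4, 4), (0, 0, 4, 4)) == 1.0

    def test_hand_value(self):
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_disjoint(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_degenerate_rejected(self):
        with pytest.raises(ValueError):
            iou((0, 0, 0, 1), (0, 0, 1, 1))


class TestNMS:
    def test_single_kept(self):
        d = [det((0, 0, 10, 10))]
        assert nms(d) == d

    def test_overlap_suppressed(self):
        d = [det((0, 0, 10, 10), conf=0.9), det((0, 0, 10, 8), conf=0.8)]
        kept = nms(d, 0.7)                       # IoU 0.8 > 0.7
        assert len(kept) == 1 and kept[0].confidence == 0.9

    def test_different_classes_not_suppressed(self):
        d = [det((0, 0, 10, 10), cls=0, conf=0.9),
             det((0, 0, 10, 8), cls=1, conf=0.8)]
        assert len(nms(d, 0.7)) == 2

    def test_empty(self):
        assert nms([]) == []

    def test_matches_brute_force_oracle(self, rng):
        dets = []
        for _ in range(50):
            x1, y1 = rng.uniform(0, 80, 2)
            w, h = rng.uniform(5, 40, 2)
            dets.append(det((x1, y1, x1 + w, y1 + h),
                            cls=int(rng.integers(0, 3)),
                            conf=float(rng.random())))
        got = nms(dets, 0.5)
        # O(n^2) oracle: independently replay greedy suppression
        order = sorted(range(50), key=lambda i: (-dets[i].confidence, i))
        keep = []
        for i in order:
            if all(dets[j].class_id != dets[i].class_id
                   or iou(dets[j].box, dets[i].box) <= 0.5 for j in keep):
                keep.append(i)
        want = [dets[i] for i in sorted(keep)]
        assert got == want

    def test_raising_threshold_never_drops_boxes(self, rng):
        dets = [det((float(x), 0.0, float(x) + 20, 20.0),
                    conf=float(c))
                for x, c in zip(rng.uniform(0, 50, 30), rng.random(30))]
        counts = [len(nms(dets, t)) for t in (0.3, 0.5, 0.7, 0.9)]
        assert counts == sorted(counts)


class TestPRCounts:
    def test_precision_example(self):
        truths = [gt((i * 20, 0, i * 20 + 10, 10), img=i) for i in range(9)]
        dets = [det((i * 20, 0, i * 20 + 10, 10), img=i) for i in range(9)]
        dets.append(det((500, 500, 510, 510), img=0))     # one spurious
        res = pr_counts(dets, truths, 0.5)
        assert res.precision == pytest.approx(90.0)

    def test_recall_boundary_no_detections(self):
        res = pr_counts([], [gt((0, 0, 5, 5))] * 5, 0.5)
        assert res.recall == 0.0 and not res.precision_defined

    def test_tp_fn_partition(self):
        truths = [gt((0, 0, 10, 10)), gt((20, 20, 30, 30))]
        dets = [det((0, 0, 10, 10), conf=0.9)]
        res = pr_counts(dets, truths, 0.5)
        assert res.tp + res.fn == len(truths)

    def test_matches_assignment_enumeration(self):
        """Crafted 6-detection scene vs exhaustive one-to-one matching."""
        truths = [gt((0, 0, 10, 10)), gt((20, 0, 30, 10)),
                  gt((40, 0, 50, 10))]
        dets = [det((0, 0, 10, 10), conf=0.95),
                det((1, 0, 11, 10), conf=0.90),      # duplicate of t0
                det((20, 0, 30, 10), conf=0.85),
                det((60, 0, 70, 10), conf=0.80),     # background
                det((40, 2, 50, 12), conf=0.75),     # iou 8/12 with t2
                det((40, 8, 50, 18), conf=0.70)]     # iou too small
        res = pr_counts(dets, truths, 0.5)
        # enumeration: t0 taken by 0.95, duplicate FP; t1 matched; t2
        # matched at 0.75; others FP
        assert (res.tp, res.fp, res.fn) == (3, 3, 0)


class TestAveragePrecision:
    def test_perfect_detector(self):
        truths = [gt((i * 20, 0, i * 20 + 10, 10), img=i) for i in range(4)]
        dets = [det((i * 20, 0, i * 20 + 10, 10), conf=0.9 - i * 0.1, img=i)
                for i in range(4)]
        assert average_precision(class_pr_curve(dets, truths, 0)) == 1.0

    def test_zero_tp(self):
        truths = [gt((0, 0, 10, 10))]
        dets = [det((50, 50, 60, 60), conf=0.9)]
        assert average_precision(class_pr_curve(dets, truths, 0)) == 0.0

    def test_matches_threshold_sweep_oracle(self):
        """Five detections; AP equals the exhaustive all-thresholds sweep of
        the interpolated precision at 101 recall points."""
        truths = [gt((i * 20, 0, i * 20 + 10, 10), img=i) for i in range(3)]
        dets = [det((0, 0, 10, 10), conf=0.9, img=0),        # TP
                det((2, 0, 12, 10), conf=0.8, img=0),        # dup FP
                det((20, 0, 30, 10), conf=0.7, img=1),       # TP
                det((90, 0, 99, 9), conf=0.6, img=2),        # FP
                det((40, 0, 50, 10), conf=0.5, img=2)]       # TP
        got = average_precision(class_pr_curve(dets, truths, 0))
        flags = [True, False, True, False, True]
        precs, recs = [], []
        for k in range(1, 6):
            tp = sum(flags[:k])
            precs.append(tp / k)
            recs.append(tp / 3)
        total = 0.0
        for r in np.linspace(0, 1, 101):
            p_at = [p for p, rr in zip(precs, recs) if rr >= r]
            total += max(p_at) if p_at else 0.0
        assert got == pytest.approx(total / 101)

    def test_invariant_to_monotone_confidence_rescale(self):
        truths = [gt((i * 20, 0, i * 20 + 10, 10), img=i) for i in range(3)]
        dets = [det((0, 0, 10, 10), conf=0.9, img=0),
                det((95, 0, 99, 9), conf=0.6, img=1),
                det((40, 0, 50, 10), conf=0.5, img=2)]
        a = average_precision(class_pr_curve(dets, truths, 0))
        squashed = [Detection(d.box, d.class_id, d.confidence ** 3,
                              d.image_id) for d in dets]
        b = average_precision(class_pr_curve(squashed, truths, 0))
        assert a == b


class TestMAP:
    def test_mean_of_ones(self):
        assert map_score({0: 1.0, 1: 1.0}) == 1.0

    def test_hand_mean(self):
        assert map_score({0: 1.0, 1: 0.5}) == 0.75

    def test_absent_class_excluded(self):
        assert map_score({0: 1.0, 1: float("nan")}) == 1.0

    def test_empty_grid_rejected(self):
        with pytest.raises(ValueError):
            evaluate_detections([], [gt((0, 0, 5, 5))], iou_grid=[])

    def test_map5095_never_exceeds_map50(self, rng):
        truths, dets = [], []
        for i in range(12):
            x = float(rng.uniform(0, 100))
            truths.append(gt((x, 0, x + 20, 20), cls=i % 3, img=i))
            jitter = float(rng.uniform(-4, 4))
            dets.append(det((x + jitter, jitter, x + 20 + jitter,
                             20 + jitter), cls=i % 3,
                            conf=float(rng.random()), img=i))
        rep = evaluate_detections(dets, truths)
        assert rep["map50_95"] <= rep["map50"] + 1e-12


class TestTheoreticalFPS:
    @pytest.mark.parametrize("latency,fps", [
        (13.26, 75.41), (12.40, 80.65), (1000.0, 1.00)])
    def test_reported_values(self, latency, fps):
        assert theoretical_fps(latency) == fps

    def test_rejects_nonpositive(self):
        with pytest.raises(ValueError):
            theoretical_fps(0.0)
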