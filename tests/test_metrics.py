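"""CLEAR-MOT scoring against hand-built fixtures and an independent
event-by-event tally; PR aggregation; annotation quality rules."""

import numpy as np
import pytest

from herdtrack.core import BoundingBox, Detection
from herdtrack.metrics import (
    FrameAnnotations,
    GtObject,
    annotation_quality_filter,
    clear_mot,
    detection_pr,
    occlusion_class,
    pr_metrics,
)


def _box(i, frame=0):
    return BoundingBox(100 * i + frame * 2.0, 50 * i, 20, 20)


def perfect_scenario(n_ids=2, n_frames=10):
    gt, hyp = [], {}
    for f in range(n_frames):
        gt.append(
            FrameAnnotations(f, [GtObject(i + 1, _box(i, f)) for i in range(n_ids)])
        )
        hyp[f] = [(i + 1, _box(i, f)) for i in range(n_ids)]
    return gt, hyp


class TestClearMot:
    def test_perfect_tracking(self):
        gt, hyp = perfect_scenario()
        m = clear_mot(gt, hyp)
        assert m.mota == 1.0 and m.motp == 1.0
        assert m.fp == m.fn == m.idsw == m.fm == 0
        assert m.mt == 2 and m.ml == 0

    def test_empty_hypotheses(self):
        gt, _ = perfect_scenario(n_ids=2, n_frames=10)  # 20 gt boxes
        m = clear_mot(gt, {})
        assert m.mota == 0.0
        assert m.fn == 20 and m.fp == 0
        assert m.ml == 2 and m.mt == 0

    def test_planted_events_mota(self):
        """10 frames, 2 identities (20 GT boxes), with exactly 1 FP, 2 FN
        and 1 identity switch planted -> MOTA = 1 - 4/20 = 0.8."""
        gt, hyp = perfect_scenario(n_ids=2, n_frames=10)
        del hyp[3][1]          # FN at frame 3 for gt 2
        del hyp[4][1]          # FN at frame 4 for gt 2
        hyp[6] = [hyp[6][0], (9, hyp[6][1][1])]   # gt 2 covered by new id 9
        for f in range(7, 10):
            hyp[f] = [hyp[f][0], (9, hyp[f][1][1])]
        hyp[5] = hyp[5] + [(7, BoundingBox(400, 400, 20, 20))]  # FP at frame 5
        m = clear_mot(gt, hyp)
        assert (m.fp, m.fn, m.idsw) == (1, 2, 1)
        assert m.mota == pytest.approx(0.8)
        # the FN gap (frames 3-4) interrupts gt 2's coverage once
        assert m.fm == 1

    def test_fragmentation_counting(self):
        gt, hyp = perfect_scenario(n_ids=1, n_frames=10)
        for f in (3, 4, 7):
            hyp[f] = []
        m = clear_mot(gt, hyp)
        assert m.fm == 2  # two separate gaps, both inside matched spans
        # trailing gap does not fragment
        gt2, hyp2 = perfect_scenario(n_ids=1, n_frames=10)
        hyp2[9] = []
        assert clear_mot(gt2, hyp2).fm == 0

    def test_mt_ml_boundaries(self):
        """Exactly 80% coverage counts as mostly-tracked; exactly 20% is
        not mostly-lost."""
        gt, hyp = perfect_scenario(n_ids=1, n_frames=10)
        for f in (8, 9):
            hyp[f] = []   # covered 8/10 = 80%
        m = clear_mot(gt, hyp)
        assert m.mt == 1
        gt2, hyp2 = perfect_scenario(n_ids=1, n_frames=10)
        for f in range(2, 10):
            hyp2[f] = []  # covered 2/10 = 20%
        m2 = clear_mot(gt2, hyp2)
        assert m2.ml == 0

    def test_match_continuity_prevents_phantom_switches(self):
        """When two hypotheses both overlap a GT box, the previous-frame
        pairing persists even if the other is momentarily closer."""
        gt = []
        hyp = {}
        for f in range(6):
            box = BoundingBox(100, 100, 20, 20)
            gt.append(FrameAnnotations(f, [GtObject(1, box)]))
            near = (1, BoundingBox(101, 100, 20, 20))
            nearer = (2, BoundingBox(100.5, 100, 20, 20)) if f >= 3 else None
            hyp[f] = [near] + ([nearer] if nearer else [])
        m = clear_mot(gt, hyp)
        assert m.idsw == 0

    def test_mota_decreases_with_injected_fps(self):
        gt, hyp = perfect_scenario(n_ids=2, n_frames=10)
        last = clear_mot(gt, hyp).mota
        for n_fp in (1, 3, 5):
            hyp_fp = {f: list(v) for f, v in hyp.items()}
            for k in range(n_fp):
                hyp_fp[k] = hyp_fp[k] + [(50 + k, BoundingBox(400, 400, 10, 10))]
            mota = clear_mot(gt, hyp_fp).mota
            assert mota < last
            last = mota

    def test_motp_invariant_to_frame_permutation(self):
        gt, hyp = perfect_scenario(n_ids=2, n_frames=8)
        m1 = clear_mot(gt, hyp)
        m2 = clear_mot(list(reversed(gt)), hyp)
        assert m1.motp == pytest.approx(m2.motp)

    def test_empty_ground_truth_rejected(self):
        with pytest.raises(ValueError):
            clear_mot([FrameAnnotations(0, [])], {})

    def test_counts_agree_with_bruteforce_tally(self):
        """Random small scenarios: FP+FN from clear_mot equal an
        independent per-frame greedy-free tally of box coverage."""
        rng = np.random.default_rng(17)
        for _ in range(10):
            n_frames, n_ids = 20, int(rng.integers(1, 5))
            gt, hyp = [], {}
            for f in range(n_frames):
                objs, hobjs = [], []
                for i in range(n_ids):
                    box = BoundingBox(100 * i, 40 * i + f, 20, 20)
                    objs.append(GtObject(i + 1, box))
                    if rng.random() > 0.2:
                        hobjs.append((i + 1, box))  # identical box when present
                if rng.random() < 0.2:
                    hobjs.append((99, BoundingBox(500, 500, 10, 10)))
                gt.append(FrameAnnotations(f, objs))
                hyp[f] = hobjs
            m = clear_mot(gt, hyp)
            # oracle: with identical boxes, coverage is exact set arithmetic
            fn = sum(
                len(frame.objects) - sum(1 for tid, _ in hyp[frame.frame_index] if tid <= n_ids)
                for frame in gt
            )
            fp = sum(
                sum(1 for tid, _ in hyp[f] if tid > n_ids) for f in range(n_frames)
            )
            assert m.fn == fn and m.fp == fp and m.idsw == 0


class FakeTracker:
    """Passes detections straight through as single-frame 'tracks'."""

    def __init__(self, gt):
        self._gt = gt

    def run(self, detections_per_frame):
        from herdtrack.tracker import FrameResult

        out = []
        for f, dets in enumerate(detections_per_frame):
            out.append(
                FrameResult(
                    f, [(1 + i, d.box, d.confidence) for i, d in enumerate(dets)]
                )
            )
        return out


class TestPrMetrics:
    def _gt_and_dets(self):
        gt = []
        dets = []
        for f in range(10):
            box = BoundingBox(100 + 2 * f, 50, 20, 20)
            gt.append(FrameAnnotations(f, [GtObject(1, box)]))
            dets.append([Detection(box, 0.95)])
        return gt, dets

    def test_invariant_output_equals_single_threshold(self):
        """If every threshold yields the same tracking output, each
        PR-metric equals its constant value."""
        gt, dets = self._gt_and_dets()
        pr, table = pr_metrics(
            gt, dets, lambda: FakeTracker(gt), threshold_grid=[0.0, 0.3, 0.6]
        )
        assert pr["PR-MOTA"] == pytest.approx(table["MOTA"].iloc[0])
        assert pr["PR-MOTP"] == pytest.approx(1.0)

    def test_two_point_trapezoid(self):
        """With two operating points of different recall, PR-MOTA is the
        trapezoidal mean of the two MOTA values."""
        gt = []
        dets = []
        for f in range(10):
            box = BoundingBox(100, 50, 20, 20)
            gt.append(FrameAnnotations(f, [GtObject(1, box)]))
            conf = 0.9 if f < 5 else 0.4   # half the detections are low-conf
            dets.append([Detection(box, conf)])
        pr, table = pr_metrics(
            gt, dets, lambda: FakeTracker(gt), threshold_grid=[0.0, 0.5]
        )
        motas = table["MOTA"].to_numpy()
        assert pr["PR-MOTA"] == pytest.approx(np.mean(motas))

    def test_grid_too_small_rejected(self):
        gt, dets = self._gt_and_dets()
        with pytest.raises(ValueError):
            pr_metrics(gt, dets, lambda: FakeTracker(gt), threshold_grid=[0.5])

    def test_detection_pr_counts(self):
        gt, dets = self._gt_and_dets()
        dets[0].append(Detection(BoundingBox(400, 400, 10, 10), 0.5))
        precision, recall = detection_pr(gt, dets)
        assert recall == pytest.approx(1.0)
        assert precision == pytest.approx(10 / 11)


class TestAnnotationFilter:
    def test_rule_examples(self):
        frames = [
            FrameAnnotations(
                0,
                [
                    GtObject(1, BoundingBox(0, 0, 10, 10), 0.0, 0.6),   # truncated
                    GtObject(2, BoundingBox(20, 0, 10, 10), 0.40, 0.0), # partial
                    GtObject(3, BoundingBox(40, 0, 10, 10), 0.0, 0.0),  # clean
                    GtObject(4, BoundingBox(60, 0, 10, 10), 0.7, 0.0),  # heavy
                ],
            )
        ]
        filtered, labels = annotation_quality_filter(frames)
        kept_ids = [o.gt_id for o in filtered[0].objects]
        assert kept_ids == [2, 3]
        assert labels[(0, 1)] == "none"
        assert labels[(0, 2)] == "partial"
        assert labels[(0, 3)] == "none"
        assert labels[(0, 4)] == "heavy"

    def test_randomized_table_boundaries(self):
        """1000 random records: discard iff truncation > 0.5 or occlusion >
        0.5; occlusion classes split at 0 and 0.5."""
        rng = np.random.default_rng(23)
        frames = []
        records = []
        for f in range(100):
            objs = []
            for i in range(10):
                occ = float(rng.choice([0.0, rng.uniform(0, 1), 0.5, 0.5000001]))
                trunc = float(rng.choice([0.0, rng.uniform(0, 1)]))
                objs.append(GtObject(i + 1, BoundingBox(20 * i, 0, 10, 10), occ, trunc))
                records.append((f, i + 1, occ, trunc))
            frames.append(FrameAnnotations(f, objs))
        filtered, labels = annotation_quality_filter(frames)
        kept = {
            (fr.frame_index, o.gt_id) for fr in filtered for o in fr.objects
        }
        for f, gid, occ, trunc in records:
            should_keep = not (trunc > 0.5 or occ > 0.5)
            assert ((f, gid) in kept) == should_keep
            expected = "none" if occ <= 0 else ("partial" if occ <= 0.5 else "heavy")
            assert labels[(f, gid)] == expected

    def test_occlusion_class_boundaries(self):
        assert occlusion_class(0.0) == "none"
        assert occlusion_class(0.5) == "partial"
        assert occlusion_class(0.5000001) == "heavy"
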