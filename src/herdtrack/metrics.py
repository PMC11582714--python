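"""CLEAR-MOT evaluation and its PR- (precision/recall-swept) variants.

Scores a tracker's output against ground-truth annotations with the CLEAR
protocol: per frame, ground-truth objects and hypotheses are matched by
intersection-over-union at a configurable threshold, previous-frame pairings
persisting whenever still admissible, and the remainder resolved by
minimum-cost assignment.  From the per-frame events the summary accumulates

* FP -- hypotheses matching no ground truth,
* FN -- ground-truth objects left uncovered,
* IDSw -- a covered ground-truth identity whose hypothesis id changed,
* FM -- interruptions of a ground-truth identity's coverage
  (matched -> unmatched -> matched),

with ``MOTA = 1 - (FN + FP + IDSw) / n_gt`` and MOTP the mean overlap of
matched pairs.  MT counts identities covered in at least 80% of their
lifetime, ML those covered in under 20%.

The PR- variants rerun the tracker over a grid of detection-confidence
thresholds and average each metric along the resulting precision-recall
operating curve (trapezoidal mean over recall, arithmetic mean when recall
does not vary).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .core import BoundingBox, Detection, iou, iou_matrix
from .association import CostMatrix, solve_assignment
from .tracker import FrameResult

__all__ = [
    "GtObject",
    "FrameAnnotations",
    "MotSummary",
    "clear_mot",
    "detection_pr",
    "pr_metrics",
    "count_false_positive_tracks",
    "annotation_quality_filter",
    "occlusion_class",
]


@dataclass(frozen=True)
class GtObject:
    gt_id: int
    box: BoundingBox
    occlusion_fraction: float = 0.0
    truncation_fraction: float = 0.0


@dataclass(frozen=True)
class FrameAnnotations:
    frame_index: int
    objects: list[GtObject]

    def __post_init__(self) -> None:
        ids = [o.gt_id for o in self.objects]
        if len(ids) != len(set(ids)):
            raise ValueError(f"duplicate gt ids in frame {self.frame_index}")


@dataclass(frozen=True)
class MotSummary:
    mota: float
    motp: float
    mt: int
    ml: int
    fp: int
    fn: int
    idsw: int
    fm: int
    gt_count: int

    def as_dict(self) -> dict:
        return {
            "MOTA": self.mota, "MOTP": self.motp, "MT": self.mt, "ML": self.ml,
            "FP": self.fp, "FN": self.fn, "IDSw": self.idsw, "FM": self.fm,
            "GT": self.gt_count,
        }


def _hyp_by_frame(
    hyp: Sequence[FrameResult] | dict[int, list[tuple[int, BoundingBox]]],
) -> dict[int, list[tuple[int, BoundingBox]]]:
    if isinstance(hyp, dict):
        return hyp
    out: dict[int, list[tuple[int, BoundingBox]]] = {}
    for fr in hyp:
        out[fr.frame_index] = [(tid, box) for tid, box, _ in fr.confirmed_tracks]
    return out


def clear_mot(
    gt: Sequence[FrameAnnotations],
    hyp: Sequence[FrameResult] | dict[int, list[tuple[int, BoundingBox]]],
    iou_match_threshold: float = 0.5,
) -> MotSummary:
    """Score tracking output against ground truth with the CLEAR protocol."""
    hyp_frames = _hyp_by_frame(hyp)
    gt_count = sum(len(f.objects) for f in gt)
    if gt_count == 0:
        raise ValueError("cannot score against empty ground truth")

    fp = fn = idsw = 0
    matched_overlaps: list[float] = []
    last_hyp_for_gt: dict[int, int] = {}       # last hypothesis id per gt id
    prev_pairs: dict[int, int] = {}            # gt id -> hyp id from prev frame
    presence: dict[int, int] = {}              # frames each gt id exists
    covered: dict[int, int] = {}               # frames each gt id is matched
    coverage_seq: dict[int, list[bool]] = {}   # per gt id matched-flags

    for frame in sorted(gt, key=lambda f: f.frame_index):
        gt_objs = frame.objects
        hyp_objs = hyp_frames.get(frame.frame_index, [])
        n_g, n_h = len(gt_objs), len(hyp_objs)
        hyp_ids = [h[0] for h in hyp_objs]
        hyp_boxes = [h[1] for h in hyp_objs]

        pairs: dict[int, int] = {}  # gt index -> hyp index this frame
        used_h: set[int] = set()

        # continuity: keep previous pairings that are still admissible
        gid_to_idx = {o.gt_id: k for k, o in enumerate(gt_objs)}
        hid_to_idx = {hid: k for k, hid in enumerate(hyp_ids)}
        for gid, hid in prev_pairs.items():
            gi = gid_to_idx.get(gid)
            hi = hid_to_idx.get(hid)
            if gi is None or hi is None or hi in used_h:
                continue
            ov = iou(gt_objs[gi].box, hyp_boxes[hi])
            if ov >= iou_match_threshold:
                pairs[gi] = hi
                used_h.add(hi)
                matched_overlaps.append(ov)

        # minimum-cost assignment for the remainder
        free_g = [k for k in range(n_g) if k not in pairs]
        free_h = [k for k in range(n_h) if k not in used_h]
        if free_g and free_h:
            overlap = iou_matrix(
                [gt_objs[k].box for k in free_g], [hyp_boxes[k] for k in free_h]
            )
            cost = CostMatrix(
                values=1.0 - overlap, gate_mask=overlap >= iou_match_threshold
            )
            sub, _, _ = solve_assignment(cost)
            for r, c in sub:
                pairs[free_g[r]] = free_h[c]
                used_h.add(free_h[c])
                matched_overlaps.append(overlap[r, c])

        fp += n_h - len(used_h)
        fn += n_g - len(pairs)

        new_prev: dict[int, int] = {}
        for k, obj in enumerate(gt_objs):
            presence[obj.gt_id] = presence.get(obj.gt_id, 0) + 1
            seq = coverage_seq.setdefault(obj.gt_id, [])
            if k in pairs:
                hid = hyp_ids[pairs[k]]
                if obj.gt_id in last_hyp_for_gt and last_hyp_for_gt[obj.gt_id] != hid:
                    idsw += 1
                last_hyp_for_gt[obj.gt_id] = hid
                covered[obj.gt_id] = covered.get(obj.gt_id, 0) + 1
                new_prev[obj.gt_id] = hid
                seq.append(True)
            else:
                seq.append(False)
        prev_pairs = new_prev

    # fragmentations: unmatched runs strictly between matched frames
    fm = 0
    for seq in coverage_seq.values():
        in_gap = False
        seen_match = False
        for matched in seq:
            if matched:
                if in_gap and seen_match:
                    fm += 1
                in_gap = False
                seen_match = True
            elif seen_match:
                in_gap = True

    mt = ml = 0
    for gid, n_present in presence.items():
        frac = covered.get(gid, 0) / n_present
        if frac >= 0.8:
            mt += 1
        if frac < 0.2:
            ml += 1

    motp = float(np.mean(matched_overlaps)) if matched_overlaps else 0.0
    mota = 1.0 - (fn + fp + idsw) / gt_count
    return MotSummary(
        mota=mota, motp=motp, mt=mt, ml=ml, fp=fp, fn=fn, idsw=idsw, fm=fm,
        gt_count=gt_count,
    )


def detection_pr(
    gt: Sequence[FrameAnnotations],
    detections_per_frame: Sequence[list[Detection]],
    iou_match_threshold: float = 0.5,
) -> tuple[float, float]:
    """Frame-wise detection precision and recall against ground truth."""
    tp = 0
    n_det = sum(len(d) for d in detections_per_frame)
    n_gt = sum(len(f.objects) for f in gt)
    gt_by_frame = {f.frame_index: f.objects for f in gt}
    for k, dets in enumerate(detections_per_frame):
        objs = gt_by_frame.get(k, [])
        if not objs or not dets:
            continue
        overlap = iou_matrix([o.box for o in objs], [d.box for d in dets])
        cost = CostMatrix(
            values=1.0 - overlap, gate_mask=overlap >= iou_match_threshold
        )
        sub, _, _ = solve_assignment(cost)
        tp += len(sub)
    precision = tp / n_det if n_det else 1.0
    recall = tp / n_gt if n_gt else 0.0
    return precision, recall


def _curve_mean(recalls: np.ndarray, values: np.ndarray) -> float:
    """Mean of a metric along the PR operating curve (trapezoid over recall)."""
    order = np.argsort(recalls, kind="stable")
    r = recalls[order]
    v = values[order]
    span = r[-1] - r[0]
    if span < 1e-12:
        return float(np.mean(v))
    return float(np.trapezoid(v, r) / span)


def pr_metrics(
    gt: Sequence[FrameAnnotations],
    raw_detections_per_frame: Sequence[list[Detection]],
    tracker_factory: Callable[[], "object"],
    threshold_grid: Sequence[float] | None = None,
    iou_match_threshold: float = 0.5,
) -> tuple[dict[str, float], pd.DataFrame]:
    """CLEAR metrics averaged over detection-confidence operating points.

    ``tracker_factory`` must return a fresh tracker exposing
    ``run(detections_per_frame) -> list[FrameResult]`` for each threshold.
    Returns the PR- summary plus the per-threshold operating table.
    """
    if threshold_grid is None:
        threshold_grid = [round(0.1 * k, 1) for k in range(10)]
    if len(threshold_grid) < 2:
        raise ValueError("threshold grid needs at least 2 points")

    rows = []
    for t in threshold_grid:
        dets_t = [
            [d for d in frame if d.confidence > t]
            for frame in raw_detections_per_frame
        ]
        precision, recall = detection_pr(gt, dets_t, iou_match_threshold)
        tracker = tracker_factory()
        results = tracker.run(dets_t)
        summary = clear_mot(gt, results, iou_match_threshold)
        row = {"threshold": t, "precision": precision, "recall": recall}
        row.update(summary.as_dict())
        rows.append(row)
    table = pd.DataFrame(rows)

    recalls = table["recall"].to_numpy(dtype=float)
    pr: dict[str, float] = {}
    for metric in ["MOTA", "MOTP", "MT", "ML", "FP", "FN", "IDSw", "FM"]:
        pr[f"PR-{metric}"] = _curve_mean(
            recalls, table[metric].to_numpy(dtype=float)
        )
    return pr, table


def count_false_positive_tracks(
    ground_truth: Sequence[FrameAnnotations],
    results: Sequence[FrameResult],
    iou_threshold: float = 0.3,
    coverage_threshold: float = 0.5,
) -> int:
    """Count confirmed track ids that do not correspond to any real target.

    A track is a false-positive trajectory when fewer than
    ``coverage_threshold`` of its reported boxes overlap some ground-truth
    box at ``iou_threshold`` or better.
    """
    gt_by_frame = {f.frame_index: [o.box for o in f.objects] for f in ground_truth}
    hits: dict[int, int] = {}
    totals: dict[int, int] = {}
    for res in results:
        gt_boxes = gt_by_frame.get(res.frame_index, [])
        for tid, box, _ in res.confirmed_tracks:
            totals[tid] = totals.get(tid, 0) + 1
            if gt_boxes and max(iou(box, g) for g in gt_boxes) >= iou_threshold:
                hits[tid] = hits.get(tid, 0) + 1
    return sum(
        1 for tid, n in totals.items()
        if hits.get(tid, 0) / n < coverage_threshold
    )


def occlusion_class(occlusion_fraction: float) -> str:
    """Classify occlusion: none (0), partial (up to half), heavy (beyond)."""
    if occlusion_fraction <= 0.0:
        return "none"
    if occlusion_fraction <= 0.5:
        return "partial"
    return "heavy"


def annotation_quality_filter(
    annotations: Sequence[FrameAnnotations],
) -> tuple[list[FrameAnnotations], dict[tuple[int, int], str]]:
    """Drop unusable annotations and label occlusion severity.

    Objects with truncation or occlusion fraction above one half are
    discarded (too unreliable to serve as ground truth); every incoming
    object is labeled ``none`` / ``partial`` / ``heavy`` keyed by
    ``(frame_index, gt_id)``.
    """
    labels: dict[tuple[int, int], str] = {}
    filtered: list[FrameAnnotations] = []
    for frame in annotations:
        kept = []
        for obj in frame.objects:
            labels[(frame.frame_index, obj.gt_id)] = occlusion_class(
                obj.occlusion_fraction
            )
            if obj.truncation_fraction > 0.5 or obj.occlusion_fraction > 0.5:
                continue
            kept.append(obj)
        filtered.append(FrameAnnotations(frame.frame_index, kept))
    return filtered, labels
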