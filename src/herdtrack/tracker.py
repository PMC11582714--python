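"""Track lifecycle management and the per-frame tracking pipeline.

A new, unassociated detection starts a *tentative* track.  Tentative tracks
must be re-associated on every following frame; once they have accumulated
``tentative_window`` matched frames they are promoted to *confirmed* -- but
only if the mean detection confidence over that window exceeds the
``mean_confidence_threshold``.  This two-stage filter (a low per-detection
threshold ``t_d`` plus a mean-confidence threshold ``t_ave_d`` at
confirmation time) lets the detector run with a permissive threshold to
avoid missing occluded animals, while spurious low-confidence detections
never graduate into reported trajectories.

Confirmed tracks that miss a detection are bridged by optical-flow
pseudo-measurements when frames are available, and are deleted once their
non-association age exceeds ``max_age``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .association import AssociationParams, iou_matching, matching_cascade
from .core import BoundingBox, CenterState, Detection, from_center_state, to_center_state
from .motion import (
    FlowParams,
    FlowPrediction,
    KalmanState,
    MotionModel,
    flow_predict_box,
    fuse_for_update,
)

__all__ = [
    "TrackStatus",
    "Track",
    "TrackerParams",
    "FrameResult",
    "pre_filter_detections",
    "decide_tentative",
    "Tracker",
]


class TrackStatus:
    TENTATIVE = "tentative"
    CONFIRMED = "confirmed"
    DELETED = "deleted"


@dataclass
class TrackerParams:
    detection_threshold: float = 0.0        # t_d
    mean_confidence_threshold: float = 0.7  # t_ave_d
    tentative_window: int = 3
    max_age: int = 30
    association: AssociationParams = field(default_factory=AssociationParams)
    use_flow_compensation: bool = False
    flow: FlowParams = field(default_factory=FlowParams)
    flow_noise_multiplier: float = 2.0
    # flow carries no identity: a pseudo-measurement is only trusted when its
    # region is unambiguously attributable to the track, i.e. no other
    # track's box overlaps it beyond this IOU.  During crossings the visible
    # texture belongs to the occluder and following it would cause switches.
    flow_overlap_suppression: float = 0.15

    def __post_init__(self) -> None:
        if not (0.0 <= self.detection_threshold <= 1.0):
            raise ValueError("detection_threshold must lie in [0, 1]")
        if not (0.0 <= self.mean_confidence_threshold <= 1.0):
            raise ValueError("mean_confidence_threshold must lie in [0, 1]")
        if self.tentative_window < 1 or self.max_age < 1:
            raise ValueError("tentative_window and max_age must be positive")


class Track:
    """One tracked identity with its motion belief and appearance gallery."""

    def __init__(
        self,
        track_id: int,
        state: KalmanState,
        confidence: float,
        feature: np.ndarray | None,
        gallery_size: int,
    ):
        self.track_id = track_id
        self.state = state
        self.status = TrackStatus.TENTATIVE
        self.non_association_age = 0
        self.frames_since_init = 0
        self.confidence_history: list[float] = [confidence]
        self.gallery: list[np.ndarray] = []
        self._gallery_size = gallery_size
        if feature is not None:
            self.gallery.append(feature)
        self.last_confidence = confidence
        self.last_box: BoundingBox | None = None
        self.projected: tuple[np.ndarray, np.ndarray] | None = None
        self.updated_this_frame = True
        self.flow_coasting = False  # bridged by flow on the previous frame

    @property
    def is_confirmed(self) -> bool:
        return self.status == TrackStatus.CONFIRMED

    @property
    def is_tentative(self) -> bool:
        return self.status == TrackStatus.TENTATIVE

    def predicted_box(self, model: MotionModel) -> BoundingBox:
        return from_center_state(model.center_state(self.state))

    def add_observation(self, detection: Detection) -> None:
        self.confidence_history.append(detection.confidence)
        self.last_confidence = detection.confidence
        if detection.feature is not None:
            self.gallery.append(detection.feature)
            if len(self.gallery) > self._gallery_size:
                del self.gallery[: len(self.gallery) - self._gallery_size]


def pre_filter_detections(
    detections: list[Detection], t_d: float
) -> list[Detection]:
    """Keep detections whose confidence strictly exceeds ``t_d``."""
    return [d for d in detections if d.confidence > t_d]


def decide_tentative(track: Track, params: TrackerParams) -> str:
    """Resolve a tentative track: ``confirm``, ``delete`` or ``keep_tentative``.

    A tentative track that missed its detection this frame is deleted
    outright.  When it has gathered ``tentative_window`` matched-frame
    confidences, it is confirmed only if their mean strictly exceeds
    ``t_ave_d``; otherwise it is deleted as a low-confidence trajectory.
    """
    if track.non_association_age > 0:
        return "delete"
    window = params.tentative_window
    if len(track.confidence_history) >= window:
        mean_conf = float(np.mean(track.confidence_history[-window:]))
        return "confirm" if mean_conf > params.mean_confidence_threshold else "delete"
    return "keep_tentative"


@dataclass(frozen=True)
class FrameResult:
    """Confirmed tracks reported for one frame."""

    frame_index: int
    confirmed_tracks: list[tuple[int, BoundingBox, float]]


class Tracker:
    """Online multi-object tracker over per-frame detections."""

    def __init__(self, params: TrackerParams | None = None, motion: MotionModel | None = None):
        self.params = params or TrackerParams()
        self.motion = motion or MotionModel()
        self.tracks: list[Track] = []
        self._next_id = 1
        self._last_frame_index: int | None = None

    # ------------------------------------------------------------------

    def _initiate(self, detection: Detection) -> Track:
        state = self.motion.initiate(to_center_state(detection.box))
        track = Track(
            track_id=self._next_id,
            state=state,
            confidence=detection.confidence,
            feature=detection.feature,
            gallery_size=self.params.association.gallery_size,
        )
        self._next_id += 1
        return track

    def _flow_for(
        self,
        track: Track,
        frame_pair: tuple[np.ndarray, np.ndarray],
    ) -> FlowPrediction | None:
        prev_box = track.last_box
        if prev_box is None:
            return None
        h_img, w_img = np.asarray(frame_pair[0]).shape
        # clip the query box into the frame; give up near the border
        x1 = max(prev_box.x, 0.0)
        y1 = max(prev_box.y, 0.0)
        x2 = min(prev_box.x2, float(w_img))
        y2 = min(prev_box.y2, float(h_img))
        if x2 - x1 < 4 or y2 - y1 < 4:
            return None
        clipped = BoundingBox(x1, y1, x2 - x1, y2 - y1)
        return flow_predict_box(frame_pair[0], frame_pair[1], clipped, self.params.flow)

    def _flow_admissible(
        self,
        track: Track,
        flow: FlowPrediction,
        measurement: CenterState,
        claimed_boxes: list[BoundingBox],
    ) -> bool:
        """Validate a flow pseudo-measurement before trusting it.

        It must fall inside the track's own motion gate, and must not lie
        mostly on a box already explained by a detection-matched track.
        """
        from .association import mahalanobis_distance
        from .core import iou

        assert track.projected is not None
        d1 = mahalanobis_distance(track.projected, [measurement])[0]
        if d1 >= self.params.association.mahalanobis_gate:
            return False
        if flow.box is not None and claimed_boxes:
            worst = max(iou(flow.box, b) for b in claimed_boxes)
            if worst > self.params.flow_overlap_suppression:
                return False
        return True

    # ------------------------------------------------------------------

    def step(
        self,
        frame_index: int,
        detections: list[Detection],
        frame_pair: tuple[np.ndarray, np.ndarray] | None = None,
    ) -> FrameResult:
        """Advance the tracker by one frame and report confirmed tracks."""
        if self._last_frame_index is not None and frame_index <= self._last_frame_index:
            raise ValueError(
                f"frame indices must strictly increase "
                f"({frame_index} after {self._last_frame_index})"
            )
        self._last_frame_index = frame_index
        params = self.params

        detections = pre_filter_detections(detections, params.detection_threshold)

        # predict phase: age every live track and cache its projection
        for track in self.tracks:
            track.state = self.motion.predict(track.state)
            track.non_association_age += 1
            track.frames_since_init += 1
            track.projected = self.motion.project(track.state)
            track.updated_this_frame = False

        confirmed = [t for t in self.tracks if t.is_confirmed]
        tentative = [t for t in self.tracks if t.is_tentative]

        # stage 1: appearance/motion cascade over confirmed tracks
        matches_c, unmatched_c_idx, unmatched_det_idx = matching_cascade(
            confirmed, detections, params.association, params.max_age
        )
        matched: list[tuple[Track, Detection]] = [
            (confirmed[i], detections[j]) for i, j in matches_c
        ]

        # stage 2: IOU matching for tentative tracks and just-missed
        # confirmed tracks on the remaining detections; a track bridged by
        # flow last frame has a current position estimate, so it keeps its
        # IOU fallback eligibility like an age-1 track
        iou_tracks = tentative + [
            confirmed[i] for i in unmatched_c_idx
            if confirmed[i].non_association_age == 1 or confirmed[i].flow_coasting
        ]
        remaining = [detections[j] for j in unmatched_det_idx]
        boxes = [t.predicted_box(self.motion) for t in iou_tracks]
        matches_i, _, unmatched_rem = iou_matching(
            boxes, remaining, params.association.iou_gate
        )
        matched.extend((iou_tracks[r], remaining[c]) for r, c in matches_i)
        unmatched_detections = [remaining[c] for c in unmatched_rem]

        matched_tracks = {id(t) for t, _ in matched}

        # the flow-coasting flag has served this frame's association
        for track in self.tracks:
            track.flow_coasting = False

        # update matched tracks
        for track, det in matched:
            measurement = fuse_for_update(det, None)
            assert measurement is not None
            track.state = self.motion.update(track.state, measurement)
            track.non_association_age = 0
            track.add_observation(det)
            track.updated_this_frame = True

        # unmatched tracks: flow pseudo-measurement (confirmed only) or coast
        claimed_boxes = [det.box for _, det in matched]
        if params.use_flow_compensation and frame_pair is not None:
            proposals: list[tuple[Track, FlowPrediction, CenterState]] = []
            for track in self.tracks:
                if id(track) in matched_tracks or not track.is_confirmed:
                    continue
                flow = self._flow_for(track, frame_pair)
                measurement = fuse_for_update(None, flow)
                if measurement is not None and self._flow_admissible(
                    track, flow, measurement, claimed_boxes
                ):
                    proposals.append((track, flow, measurement))
            # flow carries no identity: drop any proposal whose region is
            # also overlapped by another track (crossings, merges), since
            # the visible texture cannot be attributed to one identity
            from .core import iou as _iou

            ambiguous: set[int] = set()
            for a, (track_a, flow_a, _) in enumerate(proposals):
                box_a = flow_a.box
                if box_a is None:
                    ambiguous.add(a)
                    continue
                for other in self.tracks:
                    if other is track_a or other.last_box is None:
                        continue
                    if _iou(box_a, other.last_box) > params.flow_overlap_suppression:
                        ambiguous.add(a)
                        break
            for k, (track, flow, measurement) in enumerate(proposals):
                if k in ambiguous:
                    continue
                track.state = self.motion.update(
                    track.state, measurement,
                    noise_scale=params.flow_noise_multiplier,
                )
                track.updated_this_frame = True
                track.flow_coasting = True

        # new tentative tracks from leftover detections
        for det in unmatched_detections:
            self.tracks.append(self._initiate(det))

        # lifecycle: tentative decisions, then age-based deletion
        for track in self.tracks:
            if track.is_tentative:
                verdict = decide_tentative(track, params)
                if verdict == "confirm":
                    track.status = TrackStatus.CONFIRMED
                elif verdict == "delete":
                    track.status = TrackStatus.DELETED
            if track.non_association_age > params.max_age:
                track.status = TrackStatus.DELETED
        self.tracks = [t for t in self.tracks if t.status != TrackStatus.DELETED]

        # remember each live track's box for next frame's flow query
        for track in self.tracks:
            track.last_box = track.predicted_box(self.motion)

        reported = [
            (t.track_id, t.predicted_box(self.motion), t.last_confidence)
            for t in self.tracks
            if t.is_confirmed and t.updated_this_frame
        ]
        reported.sort(key=lambda item: item[0])
        return FrameResult(frame_index=frame_index, confirmed_tracks=reported)

    # ------------------------------------------------------------------

    def run(
        self,
        detections_per_frame: list[list[Detection]],
        frames: list[np.ndarray] | None = None,
    ) -> list[FrameResult]:
        """Track a whole sequence; frames (if given) enable flow compensation."""
        results = []
        for k, dets in enumerate(detections_per_frame):
            pair = None
            if frames is not None and k > 0:
                pair = (frames[k - 1], frames[k])
            results.append(self.step(k, dets, pair))
        return results
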