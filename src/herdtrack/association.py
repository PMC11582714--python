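"""Data association: gated distances, combined cost, optimal assignment,
the age-prioritized matching cascade, and IOU fallback matching.

Two complementary distances are combined per track/detection pair:

* the squared Mahalanobis distance between the track's projected
  measurement distribution and the detection box, which gates on motion;
* the appearance distance ``min_k (1 - r_j . r_k)`` between the detection's
  unit-norm feature and the track's gallery of recent features, which gates
  on identity.

The combined cost is the convex mixture ``lambda * d1 + (1 - lambda) * d2``
and a pair is admissible only when *both* distances pass their gates.  The
default mixture weight is 0 (appearance-dominant matching with the
Mahalanobis distance acting purely as a gate), the convention of the
canonical appearance-based tracker; the chi-square 0.95 quantile for 4
degrees of freedom gates the motion term.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING, Sequence

import numpy as np
from scipy.optimize import linear_sum_assignment

from .core import BoundingBox, CenterState, Detection, iou_matrix

if TYPE_CHECKING:  # pragma: no cover
    from .tracker import Track

__all__ = [
    "GATED_COST",
    "CHI2_GATE_4DOF",
    "AssociationParams",
    "CostMatrix",
    "mahalanobis_distance",
    "appearance_distance",
    "combined_cost",
    "solve_assignment",
    "matching_cascade",
    "iou_matching",
]

# Sentinel strictly larger than any admissible combined cost.
GATED_COST = 1e5

# chi-square inverse CDF at 0.95 for 4 degrees of freedom.
CHI2_GATE_4DOF = 9.4877


@dataclass(frozen=True)
class AssociationParams:
    lambda_weight: float = 0.0
    mahalanobis_gate: float = CHI2_GATE_4DOF
    appearance_gate: float = 0.2
    gallery_size: int = 100
    iou_gate: float = 0.3

    def __post_init__(self) -> None:
        if not (0.0 <= self.lambda_weight <= 1.0):
            raise ValueError("lambda_weight must lie in [0, 1]")
        if self.mahalanobis_gate <= 0:
            raise ValueError("mahalanobis_gate must be positive")
        if not (0.0 < self.appearance_gate <= 2.0):
            raise ValueError("appearance_gate must lie in (0, 2]")
        if not (0.0 < self.iou_gate < 1.0):
            raise ValueError("iou_gate must lie in (0, 1)")
        if self.gallery_size < 1:
            raise ValueError("gallery_size must be positive")


@dataclass(frozen=True)
class CostMatrix:
    """A tracks-by-detections cost with an admissibility mask."""

    values: np.ndarray
    gate_mask: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        mask = np.asarray(self.gate_mask, dtype=bool)
        if values.shape != mask.shape:
            raise ValueError("values and gate_mask must share a shape")
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "gate_mask", mask)


def mahalanobis_distance(
    projected: tuple[np.ndarray, np.ndarray],
    detections: Sequence[CenterState],
) -> np.ndarray:
    """Squared Mahalanobis distance of each detection to one projected track."""
    mean4, cov4 = projected
    mean4 = np.asarray(mean4, dtype=float)
    cov4 = np.asarray(cov4, dtype=float)
    if not detections:
        return np.zeros(0)
    z = np.stack([d.as_array() for d in detections]) - mean4[None, :]
    try:
        chol = np.linalg.cholesky(cov4)
    except np.linalg.LinAlgError as exc:
        from .motion import NumericalFailureError

        raise NumericalFailureError("projected covariance is singular") from exc
    solved = np.linalg.solve(chol, z.T)  # (4, n)
    return np.sum(solved**2, axis=0)


def appearance_distance(
    gallery: Sequence[np.ndarray],
    detection_features: Sequence[np.ndarray],
) -> np.ndarray:
    """Minimum cosine distance of each detection feature to the gallery."""
    if len(gallery) == 0:
        raise ValueError("appearance gallery must be non-empty")
    g = np.stack([np.asarray(v, dtype=float) for v in gallery])
    if len(detection_features) == 0:
        return np.zeros(0)
    r = np.stack([np.asarray(v, dtype=float) for v in detection_features])
    cos = r @ g.T  # (n_det, n_gallery)
    return np.min(1.0 - cos, axis=1)


def combined_cost(
    d1: np.ndarray, d2: np.ndarray, params: AssociationParams
) -> CostMatrix:
    """Mix motion and appearance distances and apply both gates."""
    d1 = np.asarray(d1, dtype=float)
    d2 = np.asarray(d2, dtype=float)
    if d1.shape != d2.shape:
        raise ValueError(f"distance shapes differ: {d1.shape} vs {d2.shape}")
    lam = params.lambda_weight
    values = lam * d1 + (1.0 - lam) * d2
    mask = (d1 < params.mahalanobis_gate) & (d2 < params.appearance_gate)
    return CostMatrix(values=values, gate_mask=mask)


def solve_assignment(
    cost: CostMatrix,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-total-cost one-to-one assignment restricted to admissible pairs.

    Gated-out entries get the ``GATED_COST`` sentinel for the solver and any
    such pair is stripped from the result, so the gate is exact.
    """
    n_rows, n_cols = cost.values.shape
    if n_rows == 0 or n_cols == 0:
        return [], list(range(n_rows)), list(range(n_cols))
    padded = np.where(cost.gate_mask, cost.values, GATED_COST)
    rows, cols = linear_sum_assignment(padded)
    matches = [
        (int(r), int(c)) for r, c in zip(rows, cols) if cost.gate_mask[r, c]
    ]
    matched_rows = {r for r, _ in matches}
    matched_cols = {c for _, c in matches}
    unmatched_rows = [r for r in range(n_rows) if r not in matched_rows]
    unmatched_cols = [c for c in range(n_cols) if c not in matched_cols]
    return matches, unmatched_rows, unmatched_cols


def _cascade_cost(
    tracks: Sequence["Track"],
    detections: Sequence[Detection],
    params: AssociationParams,
) -> CostMatrix:
    """Combined cost between a track subset and detections.

    Falls back to Mahalanobis-only cost when features are unavailable for
    some detection or a track has an empty gallery (the appearance gate then
    passes vacuously for those pairs).
    """
    from .core import to_center_state

    states = [to_center_state(d.box) for d in detections]
    n_t, n_d = len(tracks), len(detections)
    d1 = np.zeros((n_t, n_d))
    d2 = np.zeros((n_t, n_d))
    have_features = all(d.feature is not None for d in detections)
    feats = [d.feature for d in detections] if have_features else None
    for i, trk in enumerate(tracks):
        d1[i] = mahalanobis_distance(trk.projected, states)
        if feats is not None and len(trk.gallery) > 0:
            d2[i] = appearance_distance(trk.gallery, feats)
    if feats is None:
        # motion-only association: cost = d1, appearance gate vacuous
        mask = d1 < params.mahalanobis_gate
        return CostMatrix(values=d1, gate_mask=mask)
    return combined_cost(d1, d2, params)


def matching_cascade(
    tracks: Sequence["Track"],
    detections: Sequence[Detection],
    params: AssociationParams,
    max_age: int,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Associate tracks to detections, prioritizing recently seen tracks.

    Iterates over non-association age 1..max_age; tracks of each age compete
    only for detections still unclaimed by younger tracks.
    """
    unmatched_det = list(range(len(detections)))
    matches: list[tuple[int, int]] = []
    for age in range(1, max_age + 1):
        if not unmatched_det:
            break
        idx_t = [i for i, t in enumerate(tracks) if t.non_association_age == age]
        if not idx_t:
            continue
        det_subset = [detections[j] for j in unmatched_det]
        cost = _cascade_cost([tracks[i] for i in idx_t], det_subset, params)
        sub_matches, _, _ = solve_assignment(cost)
        claimed = set()
        for r, c in sub_matches:
            matches.append((idx_t[r], unmatched_det[c]))
            claimed.add(unmatched_det[c])
        unmatched_det = [j for j in unmatched_det if j not in claimed]
    matched_tracks = {r for r, _ in matches}
    unmatched_tracks = [i for i in range(len(tracks)) if i not in matched_tracks]
    return matches, unmatched_tracks, unmatched_det


def iou_matching(
    track_boxes: Sequence[BoundingBox],
    detections: Sequence[Detection],
    iou_gate: float,
) -> tuple[list[tuple[int, int]], list[int], list[int]]:
    """Minimum-cost matching under ``1 - IOU``, gated at ``1 - iou_gate``."""
    n_t, n_d = len(track_boxes), len(detections)
    if n_t == 0 or n_d == 0:
        return [], list(range(n_t)), list(range(n_d))
    overlap = iou_matrix(list(track_boxes), [d.box for d in detections])
    cost = CostMatrix(values=1.0 - overlap, gate_mask=overlap >= iou_gate)
    return solve_assignment(cost)
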