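"""Shared geometric and identity types for tracking-by-detection.

Pixel convention: origin at the top-left of the image, x increases rightward,
y increases downward, coordinates are 0-based reals.  Boxes are closed
real-valued regions, not integer pixel grids, which keeps intersection /
union arithmetic free of +-1 ambiguity.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

__all__ = [
    "InvalidGeometryError",
    "BoundingBox",
    "Detection",
    "CenterState",
    "to_center_state",
    "from_center_state",
    "iou",
    "iou_matrix",
]


class InvalidGeometryError(ValueError):
    """Raised for degenerate boxes (non-positive extent, non-finite coords)."""


@dataclass(frozen=True)
class BoundingBox:
    """Axis-aligned pixel-space box in top-left / width / height form."""

    x: float
    y: float
    width: float
    height: float

    def __post_init__(self) -> None:
        vals = (self.x, self.y, self.width, self.height)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidGeometryError(f"non-finite box coordinates: {vals}")
        if self.width <= 0 or self.height <= 0:
            raise InvalidGeometryError(
                f"box extent must be positive, got w={self.width}, h={self.height}"
            )

    @property
    def x2(self) -> float:
        return self.x + self.width

    @property
    def y2(self) -> float:
        return self.y + self.height

    @property
    def center(self) -> tuple[float, float]:
        return (self.x + self.width / 2.0, self.y + self.height / 2.0)

    @property
    def area(self) -> float:
        return self.width * self.height

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.width, self.height], dtype=float)


@dataclass(frozen=True)
class CenterState:
    """Box in the measurement parameterization of the motion model.

    ``(x_center, y_center, aspect_ratio, height)`` with aspect ratio
    gamma = width / height.
    """

    x_center: float
    y_center: float
    aspect_ratio: float
    height: float

    def __post_init__(self) -> None:
        vals = (self.x_center, self.y_center, self.aspect_ratio, self.height)
        if not all(math.isfinite(v) for v in vals):
            raise InvalidGeometryError(f"non-finite center state: {vals}")
        if self.height <= 0 or self.aspect_ratio <= 0:
            raise InvalidGeometryError(
                f"height and aspect ratio must be positive, got "
                f"gamma={self.aspect_ratio}, h={self.height}"
            )

    def as_array(self) -> np.ndarray:
        return np.array(
            [self.x_center, self.y_center, self.aspect_ratio, self.height],
            dtype=float,
        )


@dataclass(frozen=True)
class Detection:
    """One detector output: a box, its confidence, and an optional
    unit-norm appearance feature vector."""

    box: BoundingBox
    confidence: float
    feature: np.ndarray | None = None
    class_label: str = "target"

    def __post_init__(self) -> None:
        if not (0.0 <= self.confidence <= 1.0):
            raise ValueError(f"confidence must lie in [0, 1], got {self.confidence}")
        if self.feature is not None:
            feat = np.asarray(self.feature, dtype=float)
            norm = float(np.linalg.norm(feat))
            if abs(norm - 1.0) > 1e-6:
                raise ValueError(f"appearance feature must be unit norm, got {norm}")
            object.__setattr__(self, "feature", feat)


def to_center_state(box: BoundingBox) -> CenterState:
    """Convert a top-left box to the center / aspect-ratio / height form."""
    return CenterState(
        x_center=box.x + box.width / 2.0,
        y_center=box.y + box.height / 2.0,
        aspect_ratio=box.width / box.height,
        height=box.height,
    )


def from_center_state(state: CenterState) -> BoundingBox:
    """Inverse of :func:`to_center_state`."""
    width = state.aspect_ratio * state.height
    return BoundingBox(
        x=state.x_center - width / 2.0,
        y=state.y_center - state.height / 2.0,
        width=width,
        height=state.height,
    )


def iou(a: BoundingBox, b: BoundingBox) -> float:
    """Intersection-over-union of two boxes; symmetric, in [0, 1]."""
    ix = min(a.x2, b.x2) - max(a.x, b.x)
    iy = min(a.y2, b.y2) - max(a.y, b.y)
    if ix <= 0 or iy <= 0:
        return 0.0
    inter = ix * iy
    union = a.area + b.area - inter
    return inter / union


def iou_matrix(rows: list[BoundingBox], cols: list[BoundingBox]) -> np.ndarray:
    """Pairwise IOU, shape (len(rows), len(cols))."""
    out = np.zeros((len(rows), len(cols)), dtype=float)
    for i, a in enumerate(rows):
        for j, b in enumerate(cols):
            out[i, j] = iou(a, b)
    return out
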