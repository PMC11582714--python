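"""Shared fixtures: rendered textured blobs for flow tests and small scenarios."""

from __future__ import annotations

import numpy as np
import pytest

from herdtrack.core import BoundingBox
from herdtrack.simulator import _blit_target, _texture_patch


@pytest.fixture(scope="session")
def blob_frame_factory():
    """Render a textured elliptical blob at a given offset on a noisy
    background; noise is independent per call unless a noise seed is given."""

    patch = _texture_patch(np.random.default_rng(42))

    def make(
        shift: tuple[float, float] = (0.0, 0.0),
        box: tuple[float, float, float, float] = (100.0, 80.0, 24.0, 18.0),
        shape: tuple[int, int] = (192, 256),
        noise_seed: int | None = None,
        draw_blob: bool = True,
    ) -> tuple[np.ndarray, BoundingBox]:
        rng = np.random.default_rng(noise_seed)
        frame = 0.75 + 0.03 * rng.normal(size=shape)
        x, y, w, h = box
        moved = BoundingBox(x + shift[0], y + shift[1], w, h)
        if draw_blob:
            _blit_target(frame, moved, patch)
        return np.clip(frame, 0.0, 1.0), moved

    return make


@pytest.fixture()
def random_boxes():
    """Seeded random valid boxes for round-trip/property checks."""
    rng = np.random.default_rng(1234)

    def make(n: int) -> list[BoundingBox]:
        return [
            BoundingBox(
                x=float(rng.uniform(-50, 500)),
                y=float(rng.uniform(-50, 500)),
                width=float(rng.uniform(0.5, 120)),
                height=float(rng.uniform(0.5, 120)),
            )
            for _ in range(n)
        ]

    return make
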