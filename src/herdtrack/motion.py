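"""Motion models: constant-velocity Kalman filtering and optical-flow
box prediction.

The track state is 8-dimensional, ``(x, y, gamma, h, vx, vy, vgamma, vh)``:
bounding-box center, aspect ratio (w/h), height, and their per-frame
velocities.  The filter is the standard linear Kalman filter with a
constant-velocity transition and a linear observation of ``(x, y, gamma, h)``.
Process and measurement noise standard deviations scale with the box height,
which keeps the filter scale-invariant across object sizes; the weights
default to the widely used tracking-by-detection convention (position weight
1/20, velocity weight 1/160).

When the detector loses a target, sparse pyramidal Lucas-Kanade optical flow
tracked on a point grid inside the last box provides a pseudo-measurement
that bridges the dropout (translation from the median point displacement,
scale from the median pairwise-distance ratio, aspect ratio held fixed).
Points are validated with a forward-backward consistency check, which is far
more reliable than the LK residual alone on low-texture backgrounds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter, map_coordinates

from .core import BoundingBox, CenterState, Detection, InvalidGeometryError, to_center_state

__all__ = [
    "NumericalFailureError",
    "KalmanState",
    "MotionModel",
    "FlowParams",
    "FlowPrediction",
    "lk_track_points",
    "flow_predict_box",
    "fuse_for_update",
]


class NumericalFailureError(RuntimeError):
    """Raised when a linear solve inside the filter fails."""


@dataclass(frozen=True)
class KalmanState:
    """Gaussian belief over the 8-D motion state."""

    mean: np.ndarray        # shape (8,)
    covariance: np.ndarray  # shape (8, 8), symmetric PSD

    def __post_init__(self) -> None:
        mean = np.asarray(self.mean, dtype=float)
        cov = np.asarray(self.covariance, dtype=float)
        if mean.shape != (8,) or cov.shape != (8, 8):
            raise ValueError("KalmanState requires mean (8,) and covariance (8, 8)")
        object.__setattr__(self, "mean", mean)
        object.__setattr__(self, "covariance", cov)


def _transition_matrix() -> np.ndarray:
    f = np.eye(8)
    f[:4, 4:] = np.eye(4)  # unit frame step
    return f


_F = _transition_matrix()
_H = np.hstack([np.eye(4), np.zeros((4, 4))])


class MotionModel:
    """Height-scaled constant-velocity Kalman filter over box states."""

    def __init__(self, pos_weight: float = 1.0 / 20, vel_weight: float = 1.0 / 160):
        self.pos_weight = float(pos_weight)
        self.vel_weight = float(vel_weight)

    # -- noise scalings (all stds proportional to box height h) ------------

    def _process_std(self, h: float) -> np.ndarray:
        wp, wv = self.pos_weight, self.vel_weight
        return np.array(
            [wp * h, wp * h, 1e-2, wp * h, wv * h, wv * h, 1e-5, wv * h]
        )

    def _measurement_std(self, h: float) -> np.ndarray:
        wp = self.pos_weight
        return np.array([wp * h, wp * h, 1e-1, wp * h])

    # -- filter steps -------------------------------------------------------

    def initiate(self, measurement: CenterState) -> KalmanState:
        """Start a new track from an unassociated detection (zero velocity)."""
        z = measurement.as_array()
        mean = np.concatenate([z, np.zeros(4)])
        h = measurement.height
        wp, wv = self.pos_weight, self.vel_weight
        std = np.array(
            [
                2 * wp * h, 2 * wp * h, 1e-2, 2 * wp * h,
                10 * wv * h, 10 * wv * h, 1e-5, 10 * wv * h,
            ]
        )
        return KalmanState(mean=mean, covariance=np.diag(std**2))

    def predict(self, state: KalmanState) -> KalmanState:
        std = self._process_std(state.mean[3])
        q = np.diag(std**2)
        mean = _F @ state.mean
        cov = _F @ state.covariance @ _F.T + q
        return KalmanState(mean=mean, covariance=0.5 * (cov + cov.T))

    def project(self, state: KalmanState) -> tuple[np.ndarray, np.ndarray]:
        """Project the belief into measurement space: (mean4, cov4)."""
        std = self._measurement_std(state.mean[3])
        r = np.diag(std**2)
        mean4 = _H @ state.mean
        cov4 = _H @ state.covariance @ _H.T + r
        return mean4, 0.5 * (cov4 + cov4.T)

    def update(
        self,
        state: KalmanState,
        measurement: CenterState,
        noise_scale: float = 1.0,
    ) -> KalmanState:
        """Kalman update against an observed box.

        ``noise_scale`` multiplies the measurement noise standard deviation;
        flow pseudo-measurements use a value > 1 to express their lower
        trust relative to detector boxes.
        """
        std = self._measurement_std(state.mean[3]) * float(noise_scale)
        r = np.diag(std**2)
        mean4 = _H @ state.mean
        s = _H @ state.covariance @ _H.T + r
        try:
            chol = np.linalg.cholesky(s)
            gain = np.linalg.solve(
                chol.T, np.linalg.solve(chol, (state.covariance @ _H.T).T)
            ).T
        except np.linalg.LinAlgError as exc:  # pragma: no cover - degenerate cov
            raise NumericalFailureError("innovation covariance not invertible") from exc
        innovation = measurement.as_array() - mean4
        mean = state.mean + gain @ innovation
        cov = (np.eye(8) - gain @ _H) @ state.covariance
        return KalmanState(mean=mean, covariance=0.5 * (cov + cov.T))

    def center_state(self, state: KalmanState) -> CenterState:
        x, y, g, h = state.mean[:4]
        return CenterState(x, y, max(g, 1e-6), max(h, 1e-6))


# ---------------------------------------------------------------------------
# Sparse pyramidal Lucas-Kanade optical flow
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class FlowParams:
    """Optical flow tuning knobs (pixels unless stated)."""

    window_size: int = 15           # LK integration window (odd)
    pyramid_levels: int = 3         # number of resolutions, coarse to fine
    max_iterations: int = 15        # Gauss-Newton iterations per level
    convergence_eps: float = 0.03   # stop when the update is this small
    min_eigen_per_px: float = 1e-3  # texture test on the gradient matrix
    fb_threshold: float = 1.0       # forward-backward consistency (px)
    grid_size: int = 7              # grid_size^2 sample points per box
    min_tracked_fraction: float = 0.5


@dataclass(frozen=True)
class FlowPrediction:
    """Flow-predicted box for one track."""

    box: BoundingBox | None
    valid: bool
    tracked_fraction: float


def _pyramid(image: np.ndarray, levels: int) -> list[np.ndarray]:
    img = np.asarray(image, dtype=float)
    pyr = [img]
    for _ in range(levels - 1):
        if min(pyr[-1].shape) < 16:
            break
        smoothed = gaussian_filter(pyr[-1], sigma=1.0, mode="nearest")
        pyr.append(smoothed[::2, ::2])
    return pyr


def _sample(image: np.ndarray, coords: np.ndarray) -> np.ndarray:
    # coords: (..., 2) in (x, y); map_coordinates wants (row, col)
    flat = coords.reshape(-1, 2)
    vals = map_coordinates(
        image, [flat[:, 1], flat[:, 0]], order=1, mode="nearest"
    )
    return vals.reshape(coords.shape[:-1])


def _lk_single_level(
    prev: np.ndarray,
    nxt: np.ndarray,
    points: np.ndarray,
    guess: np.ndarray,
    params: FlowParams,
) -> tuple[np.ndarray, np.ndarray]:
    """One pyramid level of iterative LK. Returns (displacements, ok)."""
    n = len(points)
    w = params.window_size // 2
    ax = np.arange(-w, w + 1, dtype=float)
    ox, oy = np.meshgrid(ax, ax)
    offsets = np.stack([ox.ravel(), oy.ravel()], axis=-1)  # (W^2, 2)
    npix = offsets.shape[0]

    gy, gx = np.gradient(prev)
    base = points[:, None, :] + offsets[None, :, :]  # (n, W^2, 2)
    patch_i = _sample(prev, base)
    patch_ix = _sample(gx, base)
    patch_iy = _sample(gy, base)

    gxx = np.sum(patch_ix**2, axis=1)
    gxy = np.sum(patch_ix * patch_iy, axis=1)
    gyy = np.sum(patch_iy**2, axis=1)
    trace = gxx + gyy
    det = gxx * gyy - gxy**2
    # smaller eigenvalue of the 2x2 structure tensor, per pixel
    eig_min = (trace - np.sqrt(np.maximum(trace**2 - 4 * det, 0.0))) / 2.0
    ok = eig_min / npix > params.min_eigen_per_px

    d = guess.astype(float).copy()
    inv_det = np.where(det > 1e-12, 1.0 / np.maximum(det, 1e-12), 0.0)
    for _ in range(params.max_iterations):
        patch_j = _sample(nxt, base + d[:, None, :])
        diff = patch_i - patch_j
        bx = np.sum(diff * patch_ix, axis=1)
        by = np.sum(diff * patch_iy, axis=1)
        step_x = inv_det * (gyy * bx - gxy * by)
        step_y = inv_det * (-gxy * bx + gxx * by)
        step = np.stack([step_x, step_y], axis=-1)
        step = np.where(ok[:, None], step, 0.0)
        d += step
        if np.all(np.linalg.norm(step, axis=-1) < params.convergence_eps):
            break

    h_img, w_img = prev.shape
    inside = (
        (points[:, 0] + d[:, 0] >= 0)
        & (points[:, 0] + d[:, 0] <= w_img - 1)
        & (points[:, 1] + d[:, 1] >= 0)
        & (points[:, 1] + d[:, 1] <= h_img - 1)
    )
    return d, ok & inside


def _lk_pyramidal(
    prev: np.ndarray,
    nxt: np.ndarray,
    points: np.ndarray,
    params: FlowParams,
) -> tuple[np.ndarray, np.ndarray]:
    pyr_prev = _pyramid(prev, params.pyramid_levels)
    pyr_next = _pyramid(nxt, params.pyramid_levels)
    levels = min(len(pyr_prev), len(pyr_next))
    d = np.zeros_like(points, dtype=float)
    ok = np.ones(len(points), dtype=bool)
    for lvl in range(levels - 1, -1, -1):
        scale = 2.0**lvl
        d_lvl, ok_lvl = _lk_single_level(
            pyr_prev[lvl], pyr_next[lvl], points / scale, d / scale, params
        )
        d = d_lvl * scale
        ok &= ok_lvl
    return d, ok


def lk_track_points(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    points: np.ndarray | list,
    params: FlowParams | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Track sparse points from ``prev_frame`` to ``next_frame``.

    Returns ``(new_points, status)`` where status combines the texture test
    and a forward-backward consistency check: a point passes only if
    re-tracking its destination back to the first frame lands within
    ``fb_threshold`` pixels of where it started.
    """
    params = params or FlowParams()
    prev = np.asarray(prev_frame, dtype=float)
    nxt = np.asarray(next_frame, dtype=float)
    if prev.shape != nxt.shape:
        raise ValueError("frames must share a shape")
    pts = np.asarray(points, dtype=float).reshape(-1, 2)
    if len(pts) == 0:
        return pts.copy(), np.zeros(0, dtype=bool)

    d_fwd, ok_fwd = _lk_pyramidal(prev, nxt, pts, params)
    fwd = pts + d_fwd
    d_bwd, ok_bwd = _lk_pyramidal(nxt, prev, fwd, params)
    back = fwd + d_bwd
    fb_err = np.linalg.norm(back - pts, axis=-1)
    status = ok_fwd & ok_bwd & (fb_err < params.fb_threshold)
    return fwd, status


def _box_grid(box: BoundingBox, grid_size: int) -> np.ndarray:
    # sample strictly inside the box, away from the boundary
    fx = np.linspace(0.15, 0.85, grid_size)
    gx, gy = np.meshgrid(box.x + fx * box.width, box.y + fx * box.height)
    return np.stack([gx.ravel(), gy.ravel()], axis=-1)


def flow_predict_box(
    prev_frame: np.ndarray,
    next_frame: np.ndarray,
    prev_box: BoundingBox,
    params: FlowParams | None = None,
) -> FlowPrediction:
    """Predict where ``prev_box`` moved using point flow inside it.

    Translation is the median point displacement; scale is the median ratio
    of pairwise point distances (aspect ratio is held fixed -- translation
    plus isotropic scale is the subset robustly recoverable from sparse
    flow).  Returns an invalid prediction when too few points survive.
    """
    params = params or FlowParams()
    h_img, w_img = np.asarray(prev_frame).shape
    if prev_box.x < 0 or prev_box.y < 0 or prev_box.x2 > w_img or prev_box.y2 > h_img:
        raise InvalidGeometryError("box lies outside the frame")

    pts = _box_grid(prev_box, params.grid_size)
    new_pts, status = lk_track_points(prev_frame, next_frame, pts, params)
    frac = float(np.mean(status)) if len(status) else 0.0
    if frac < params.min_tracked_fraction or status.sum() < 2:
        return FlowPrediction(box=None, valid=False, tracked_fraction=frac)

    old_ok = pts[status]
    new_ok = new_pts[status]
    disp = np.median(new_ok - old_ok, axis=0)

    from scipy.spatial.distance import pdist

    d_old = pdist(old_ok)
    d_new = pdist(new_ok)
    keep = d_old > 1e-6
    scale = float(np.median(d_new[keep] / d_old[keep])) if keep.any() else 1.0
    scale = float(np.clip(scale, 0.5, 2.0))

    cx, cy = prev_box.center
    new_w = prev_box.width * scale
    new_h = prev_box.height * scale
    box = BoundingBox(
        x=cx + disp[0] - new_w / 2.0,
        y=cy + disp[1] - new_h / 2.0,
        width=new_w,
        height=new_h,
    )
    return FlowPrediction(box=box, valid=True, tracked_fraction=frac)


def fuse_for_update(
    detection: Detection | None,
    flow: FlowPrediction | None,
) -> CenterState | None:
    """Pick the measurement the filter should be updated with.

    A matched detection always wins (detector boxes are the more accurate
    trace input); otherwise a valid flow prediction serves as a
    pseudo-measurement; with neither, the filter runs predict-only.
    """
    if detection is not None:
        return to_center_state(detection.box)
    if flow is not None and flow.valid and flow.box is not None:
        return to_center_state(flow.box)
    return None
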