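"""Synthetic herd scenarios and a kinematic vehicle/camera plant.

The generator emulates the conditions of aerial herd footage at the level
the tracker cares about: a handful of animals moving smoothly in the image
plane, a detector that jitters box coordinates, occasionally drops a target
for a few consecutive frames, and emits spurious low-confidence detections;
appearance features that are consistent within an identity but noisy.
Rendered frames (dark textured ellipses on a light noisy background --
grazing yaks are mostly black and gray seen from above) give the optical
flow something real to track.

All randomness flows from one root seed through named child streams
(trajectories, detector noise, dropouts, clutter, features, rendering), so
toggling one degradation never perturbs the others -- the basis for
controlled ablations.

The same module provides the closed-loop plant for the servo controller: a
pinhole camera on a kinematic vehicle with first-order velocity response,
and ground targets walking along concentric arcs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter, gaussian_filter1d, map_coordinates

from .core import BoundingBox, Detection
from .metrics import FrameAnnotations, GtObject
from .servo import ServoController, ServoGains, VelocityCommand

__all__ = [
    "ScenarioConfig",
    "Scenario",
    "generate_scenario",
    "render_frames",
    "CameraModel",
    "UavState",
    "project_targets",
    "uav_step",
    "ArcHerdConfig",
    "run_closed_loop",
    "dropout_benchmark_config",
    "clutter_benchmark_config",
    "demo_config",
]


# ---------------------------------------------------------------------------
# image-plane scenario generation
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ScenarioConfig:
    """Study conditions for one synthetic sequence."""

    seed: int
    n_targets: int = 2
    n_frames: int = 300
    frame_size: tuple[int, int] = (256, 192)   # (W, H) px
    trajectory_kind: str = "random_smooth"     # linear | arc | concentric_arcs | random_smooth
    speed_range: tuple[float, float] = (1.0, 2.5)   # px / frame
    turn_rate_std: float = 0.05                # rad / frame (random_smooth)
    target_size: tuple[float, float] = (22.0, 16.0)  # (w, h) px
    size_jitter: float = 0.15                  # relative per-target size spread
    detection_noise_std: float = 0.5           # px on box coordinates
    detection_conf_range: tuple[float, float] = (0.7, 0.95)
    dropout_rate: float = 0.0                  # per target per frame
    dropout_length_range: tuple[int, int] = (3, 5)
    fp_rate: float = 0.0                       # clutter spawns per frame (Poisson)
    fp_confidence_range: tuple[float, float] = (0.2, 0.4)
    fp_lifetime_mean: float = 6.0              # frames (geometric)
    occlusion_drop_threshold: float = 0.5      # heavy occlusion kills detection
    feature_dim: int = 16
    feature_noise: float = 0.1

    def __post_init__(self) -> None:
        w, h = self.frame_size
        tw, th = self.target_size
        if tw >= w or th >= h:
            raise ValueError("targets must be smaller than the frame")
        if self.n_targets < 1 or self.n_frames < 2:
            raise ValueError("need at least one target and two frames")
        for name in ("dropout_rate", "fp_rate", "detection_noise_std", "feature_noise"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        kinds = {"linear", "arc", "concentric_arcs", "random_smooth"}
        if self.trajectory_kind not in kinds:
            raise ValueError(f"trajectory_kind must be one of {sorted(kinds)}")


@dataclass
class Scenario:
    """Ground truth plus degraded detections for one synthetic sequence."""

    config: ScenarioConfig
    ground_truth: list[FrameAnnotations]
    detections: list[list[Detection]]
    target_boxes: dict[int, list[BoundingBox]]   # per id, one box per frame
    base_features: dict[int, np.ndarray]
    frames: list[np.ndarray] | None = None


def _wrap_angle(a: float) -> float:
    return (a + math.pi) % (2.0 * math.pi) - math.pi


def _trajectories(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """Smooth center paths, shape (n_targets, n_frames, 2).

    Paths are integrated from a heading process (per-kind turn-rate noise)
    with gentle steering toward the frame center near the borders, so
    trajectories stay in view without velocity discontinuities -- animals
    turn, they do not bounce.
    """
    w, h = cfg.frame_size
    tw, th = cfg.target_size
    mx, my = tw / 2 + 2, th / 2 + 2
    n, t = cfg.n_targets, cfg.n_frames
    buffer_px = max(20.0, 1.2 * tw)
    max_steer = 0.25  # rad/frame at a wall
    out = np.zeros((n, t, 2))
    for i in range(n):
        speed = rng.uniform(*cfg.speed_range)
        if cfg.trajectory_kind == "concentric_arcs":
            radius = min(30.0 + 18.0 * i, min(w, h) / 2.0 - max(mx, my) - 2)
            omega = speed / radius
            theta0 = rng.uniform(0, 2 * math.pi)
            phases = theta0 + omega * np.arange(t)
            out[i, :, 0] = w / 2.0 + radius * np.cos(phases)
            out[i, :, 1] = h / 2.0 + radius * np.sin(phases)
            continue
        if cfg.trajectory_kind == "linear":
            turn = np.zeros(t)
        elif cfg.trajectory_kind == "arc":
            radius = rng.uniform(40.0, 90.0)
            turn = np.full(t, speed / radius * rng.choice([-1.0, 1.0]))
        else:  # random_smooth
            turn = gaussian_filter1d(
                rng.normal(0.0, cfg.turn_rate_std, size=t), sigma=4.0,
                mode="nearest",
            )
        pos = np.array([rng.uniform(mx + 5, w - mx - 5), rng.uniform(my + 5, h - my - 5)])
        heading = rng.uniform(0, 2 * math.pi)
        for f in range(t):
            out[i, f] = pos
            wall = min(
                pos[0] - mx, (w - mx) - pos[0], pos[1] - my, (h - my) - pos[1]
            )
            gain = float(np.clip(1.0 - wall / buffer_px, 0.0, 1.0))
            if gain > 0:
                to_center = math.atan2(h / 2.0 - pos[1], w / 2.0 - pos[0])
                diff = _wrap_angle(to_center - heading)
                heading += gain * float(np.clip(diff, -max_steer, max_steer))
            heading += turn[f]
            pos = pos + speed * np.array([math.cos(heading), math.sin(heading)])
            pos[0] = float(np.clip(pos[0], mx, w - mx))
            pos[1] = float(np.clip(pos[1], my, h - my))
    return out


def _dropout_mask(cfg: ScenarioConfig, rng: np.random.Generator) -> np.ndarray:
    """True where the detector drops the target, shape (n_targets, n_frames)."""
    mask = np.zeros((cfg.n_targets, cfg.n_frames), dtype=bool)
    lo, hi = cfg.dropout_length_range
    for i in range(cfg.n_targets):
        f = 0
        while f < cfg.n_frames:
            if rng.random() < cfg.dropout_rate:
                run = int(rng.integers(lo, hi + 1))
                mask[i, f : f + run] = True
                f += run
            else:
                f += 1
    return mask


def _occlusion_fraction(boxes: list[BoundingBox], k: int) -> float:
    """Fraction of box k covered by the most-overlapping other box."""
    own = boxes[k]
    best = 0.0
    for j, other in enumerate(boxes):
        if j == k:
            continue
        ix = min(own.x2, other.x2) - max(own.x, other.x)
        iy = min(own.y2, other.y2) - max(own.y, other.y)
        if ix > 0 and iy > 0:
            best = max(best, ix * iy / own.area)
    return min(best, 1.0)


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def generate_scenario(config: ScenarioConfig) -> Scenario:
    """Produce ground truth and degraded detections, bit-reproducibly."""
    root = np.random.SeedSequence(config.seed)
    streams = root.spawn(5)
    rng_traj = np.random.default_rng(streams[0])
    rng_noise = np.random.default_rng(streams[1])
    rng_drop = np.random.default_rng(streams[2])
    rng_fp = np.random.default_rng(streams[3])
    rng_feat = np.random.default_rng(streams[4])

    w_img, h_img = config.frame_size
    centers = _trajectories(config, rng_traj)
    dropouts = _dropout_mask(config, rng_drop)

    tw, th = config.target_size
    sizes = [
        (
            tw * (1.0 + rng_traj.uniform(-config.size_jitter, config.size_jitter)),
            th * (1.0 + rng_traj.uniform(-config.size_jitter, config.size_jitter)),
        )
        for _ in range(config.n_targets)
    ]
    base_features = {
        i + 1: _unit(rng_feat.normal(size=config.feature_dim))
        for i in range(config.n_targets)
    }

    # clutter objects: persistent low-confidence spurious detections
    clutter: list[dict] = []
    if config.fp_rate > 0:
        for f in range(config.n_frames):
            for _ in range(rng_fp.poisson(config.fp_rate)):
                life = 1 + rng_fp.geometric(1.0 / config.fp_lifetime_mean)
                scale = rng_fp.uniform(0.7, 1.2)
                clutter.append(
                    {
                        "start": f,
                        "end": min(f + life, config.n_frames),
                        "cx": rng_fp.uniform(tw, w_img - tw),
                        "cy": rng_fp.uniform(th, h_img - th),
                        "w": tw * scale,
                        "h": th * scale,
                        "feature": _unit(rng_fp.normal(size=config.feature_dim)),
                    }
                )

    ground_truth: list[FrameAnnotations] = []
    detections: list[list[Detection]] = []
    target_boxes: dict[int, list[BoundingBox]] = {
        i + 1: [] for i in range(config.n_targets)
    }

    for f in range(config.n_frames):
        boxes = []
        for i in range(config.n_targets):
            bw, bh = sizes[i]
            cx, cy = centers[i, f]
            boxes.append(BoundingBox(cx - bw / 2, cy - bh / 2, bw, bh))
        for i, box in enumerate(boxes):
            target_boxes[i + 1].append(box)

        objs = []
        frame_dets: list[Detection] = []
        for i, box in enumerate(boxes):
            occ = _occlusion_fraction(boxes, i)
            inside_w = min(box.x2, w_img) - max(box.x, 0.0)
            inside_h = min(box.y2, h_img) - max(box.y, 0.0)
            trunc = 1.0 - max(inside_w, 0.0) * max(inside_h, 0.0) / box.area
            objs.append(GtObject(i + 1, box, occ, max(trunc, 0.0)))

            if dropouts[i, f] or occ > config.occlusion_drop_threshold:
                continue
            noise = rng_noise.normal(0.0, config.detection_noise_std, size=4)
            try:
                nbox = BoundingBox(
                    box.x + noise[0],
                    box.y + noise[1],
                    max(box.width + noise[2], 2.0),
                    max(box.height + noise[3], 2.0),
                )
            except ValueError:  # pragma: no cover - sizes clamped above
                continue
            conf = rng_noise.uniform(*config.detection_conf_range) * (1.0 - 0.4 * occ)
            feat = _unit(
                base_features[i + 1]
                + config.feature_noise * rng_feat.normal(size=config.feature_dim)
            )
            frame_dets.append(
                Detection(nbox, float(np.clip(conf, 0.01, 1.0)), feat)
            )

        for c in clutter:
            if not (c["start"] <= f < c["end"]):
                continue
            jit = rng_fp.normal(0.0, 0.3, size=2)
            cbox = BoundingBox(
                c["cx"] + jit[0] - c["w"] / 2,
                c["cy"] + jit[1] - c["h"] / 2,
                c["w"],
                c["h"],
            )
            conf = rng_fp.uniform(*config.fp_confidence_range)
            feat = _unit(
                c["feature"]
                + config.feature_noise * rng_fp.normal(size=config.feature_dim)
            )
            frame_dets.append(Detection(cbox, float(conf), feat))

        ground_truth.append(FrameAnnotations(f, objs))
        detections.append(frame_dets)

    return Scenario(
        config=config,
        ground_truth=ground_truth,
        detections=detections,
        target_boxes=target_boxes,
        base_features=base_features,
    )


# ---------------------------------------------------------------------------
# frame rendering (optical-flow test bed)
# ---------------------------------------------------------------------------


def _texture_patch(rng: np.random.Generator, size: int = 32) -> np.ndarray:
    """Dark speckled patch with enough gradient structure for LK."""
    speckle = gaussian_filter(rng.normal(size=(size, size)), sigma=1.2)
    speckle = (speckle - speckle.min()) / (np.ptp(speckle) + 1e-12)
    return 0.15 + 0.30 * speckle


def _blit_target(
    frame: np.ndarray, box: BoundingBox, patch: np.ndarray
) -> None:
    h_img, w_img = frame.shape
    x1 = max(int(math.floor(box.x)), 0)
    y1 = max(int(math.floor(box.y)), 0)
    x2 = min(int(math.ceil(box.x2)) + 1, w_img)
    y2 = min(int(math.ceil(box.y2)) + 1, h_img)
    if x2 <= x1 or y2 <= y1:
        return
    jj, ii = np.meshgrid(np.arange(x1, x2), np.arange(y1, y2))
    # normalized box coordinates of each pixel center
    u = (jj - box.x) / box.width
    v = (ii - box.y) / box.height
    cx, cy = box.center
    mask = ((jj - cx) / (box.width / 2)) ** 2 + ((ii - cy) / (box.height / 2)) ** 2 <= 1.0
    p = patch.shape[0] - 1
    vals = map_coordinates(
        patch, [np.clip(v, 0, 1).ravel() * p, np.clip(u, 0, 1).ravel() * p],
        order=1, mode="nearest",
    ).reshape(u.shape)
    region = frame[y1:y2, x1:x2]
    region[mask] = vals[mask]


def render_frames(scenario: Scenario, background_noise: float = 0.03) -> list[np.ndarray]:
    """Draw each frame: textured dark ellipses on a light noisy background.

    Texture is anchored to each target's box, so it translates and scales
    with the target at subpixel accuracy; background noise is independent
    per frame (sensor noise, not trackable structure).
    """
    cfg = scenario.config
    rng = np.random.default_rng(np.random.SeedSequence(cfg.seed).spawn(7)[6])
    patches = {
        tid: _texture_patch(rng) for tid in sorted(scenario.target_boxes)
    }
    w_img, h_img = cfg.frame_size
    frames = []
    for f in range(cfg.n_frames):
        frame = 0.75 + background_noise * rng.normal(size=(h_img, w_img))
        for tid, boxes in scenario.target_boxes.items():
            _blit_target(frame, boxes[f], patches[tid])
        frames.append(np.clip(frame, 0.0, 1.0))
    scenario.frames = frames
    return frames


# ---------------------------------------------------------------------------
# vehicle, camera and the closed servo loop
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class CameraModel:
    """Pinhole camera, rigidly mounted, tilted down from horizontal."""

    frame_size: tuple[int, int] = (640, 480)
    hfov_deg: float = 90.0
    tilt_deg: float = 45.0

    @property
    def focal(self) -> float:
        return (self.frame_size[0] / 2.0) / math.tan(math.radians(self.hfov_deg) / 2.0)


@dataclass
class UavState:
    """Kinematic vehicle state in the world frame (x east, y north, z up)."""

    position: np.ndarray = field(default_factory=lambda: np.zeros(3))
    heading: float = 0.0            # rad; 0 means body-forward = +y world
    velocity: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.position = np.asarray(self.position, dtype=float)
        self.velocity = np.asarray(self.velocity, dtype=float)


def _camera_axes(uav: UavState, camera: CameraModel) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    c, s = math.cos(uav.heading), math.sin(uav.heading)
    forward = np.array([-s, c, 0.0])
    right = np.array([c, s, 0.0])
    tau = math.radians(camera.tilt_deg)
    optical = math.cos(tau) * forward - math.sin(tau) * np.array([0.0, 0.0, 1.0])
    down = np.cross(optical, right)
    return right, down, optical


def project_targets(
    uav: UavState,
    targets_world: list[tuple[int, np.ndarray]],
    camera: CameraModel,
    target_height_m: float = 1.6,
    target_aspect: float = 1.6,
) -> list[tuple[int, BoundingBox, bool]]:
    """Project world targets to image boxes.

    Box height is focal * target_height / range along the optical axis --
    the monotone size-distance relation the longitudinal controller uses.
    Targets behind the camera are flagged invalid.
    """
    w_img, h_img = camera.frame_size
    f = camera.focal
    right, down, optical = _camera_axes(uav, camera)
    out = []
    for tid, pos in targets_world:
        pos3 = np.asarray(pos, dtype=float)
        if pos3.shape == (2,):
            pos3 = np.array([pos3[0], pos3[1], target_height_m / 2.0])
        rel = pos3 - uav.position
        zc = float(rel @ optical)
        if zc <= 0.5:
            out.append((tid, BoundingBox(0.0, 0.0, 1.0, 1.0), False))
            continue
        u = f * float(rel @ right) / zc + w_img / 2.0
        v = f * float(rel @ down) / zc + h_img / 2.0
        bh = f * target_height_m / zc
        bw = bh * target_aspect
        out.append((tid, BoundingBox(u - bw / 2, v - bh / 2, bw, bh), True))
    return out


def uav_step(
    uav: UavState, cmd: VelocityCommand, dt: float, response_time: float = 0.3
) -> UavState:
    """Advance the vehicle: first-order velocity response, kinematic pose.

    The attitude loop is abstracted as an exponential relaxation of the
    velocity toward the command with time constant ``response_time``.
    """
    if dt <= 0:
        raise ValueError("dt must be positive")
    target_v = np.array([cmd.vx_world, cmd.vy_world, cmd.vz_world])
    if response_time <= 1e-9:
        new_v = target_v
    else:
        alpha = math.exp(-dt / response_time)
        new_v = target_v + (uav.velocity - target_v) * alpha
    return UavState(
        position=uav.position + new_v * dt,
        heading=uav.heading + cmd.yaw_rate * dt,
        velocity=new_v,
    )


@dataclass(frozen=True)
class ArcHerdConfig:
    """Two ground targets walking along concentric arcs (world frame)."""

    radii: tuple[float, float] = (8.0, 12.0)
    center: tuple[float, float] = (0.0, 0.0)
    angular_speed: float = 0.05     # rad/s
    start_angle: float = math.pi / 2
    angle_offset: float = 0.0       # phase offset of the second target
    duration_s: float = 60.0
    dt: float = 0.1
    response_time: float = 0.3
    target_height_m: float = 1.6


def perpendicularity_error(uav: UavState, p1: np.ndarray, p2: np.ndarray) -> float:
    """|angle between the body-forward axis and the perpendicular of the
    inter-target connection line|, in [0, pi/2]."""
    c, s = math.cos(uav.heading), math.sin(uav.heading)
    forward = np.array([-s, c])
    d = np.asarray(p2, dtype=float)[:2] - np.asarray(p1, dtype=float)[:2]
    n = np.linalg.norm(d)
    if n < 1e-9:
        return 0.0
    return abs(math.asin(float(np.clip(forward @ (d / n), -1.0, 1.0))))


def run_closed_loop(
    herd: ArcHerdConfig | None = None,
    gains: ServoGains | None = None,
    camera: CameraModel | None = None,
    uav0: UavState | None = None,
) -> pd.DataFrame:
    """Fly the servo loop against the arc-walking herd; return the log.

    Tracking is assumed ideal (ground-truth boxes with stable ids feed the
    controller), isolating the controller's behavior from the tracker's.
    """
    herd = herd or ArcHerdConfig()
    gains = gains or ServoGains()
    camera = camera or CameraModel()
    if uav0 is None:
        # start on the far side of the herd center, looking at it
        cx, cy = herd.center
        uav0 = UavState(
            position=np.array([cx, cy - 22.0, 12.0]),
            heading=0.0,
            velocity=np.zeros(3),
        )

    controller = ServoController(gains)
    uav = uav0
    rows = []
    n_steps = int(round(herd.duration_s / herd.dt))
    for k in range(n_steps):
        t = k * herd.dt
        angles = (
            herd.start_angle + herd.angular_speed * t,
            herd.start_angle + herd.angle_offset + herd.angular_speed * t,
        )
        targets = []
        for tid, (r, ang) in enumerate(zip(herd.radii, angles), start=1):
            targets.append(
                (
                    tid,
                    np.array(
                        [
                            herd.center[0] + r * math.cos(ang),
                            herd.center[1] + r * math.sin(ang),
                            herd.target_height_m / 2.0,
                        ]
                    ),
                )
            )
        projected = project_targets(
            uav, targets, camera, target_height_m=herd.target_height_m
        )
        tracks = [(tid, box) for tid, box, ok in projected if ok]
        cmd = controller.command(
            tracks,
            camera.frame_size,
            herd.dt,
            heading=uav.heading,
            altitude=float(uav.position[2]),
        )
        perp_err = perpendicularity_error(uav, targets[0][1], targets[1][1])
        rows.append(
            {
                "t": t,
                "x": uav.position[0], "y": uav.position[1], "z": uav.position[2],
                "heading": uav.heading,
                "vx_cmd": cmd.vx_world, "vy_cmd": cmd.vy_world,
                "vz_cmd": cmd.vz_world, "yaw_rate_cmd": cmd.yaw_rate,
                "perp_error": perp_err,
                "n_visible": len(tracks),
            }
        )
        uav = uav_step(uav, cmd, herd.dt, herd.response_time)
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# frozen benchmark conditions
# ---------------------------------------------------------------------------


def dropout_benchmark_config(seed: int) -> ScenarioConfig:
    """Detector-dropout conditions: two smoothly turning targets, 300
    frames, 3-5-frame detection dropouts, no clutter."""
    return ScenarioConfig(
        seed=seed,
        n_targets=2,
        n_frames=300,
        frame_size=(256, 192),
        trajectory_kind="random_smooth",
        dropout_rate=0.02,
        dropout_length_range=(3, 5),
    )


def clutter_benchmark_config(seed: int) -> ScenarioConfig:
    """Low-confidence clutter conditions: spurious persistent detections at
    one per frame with confidence at most 0.4, no dropouts."""
    return ScenarioConfig(
        seed=seed,
        n_targets=2,
        n_frames=200,
        frame_size=(256, 192),
        trajectory_kind="random_smooth",
        fp_rate=1.0,
        fp_confidence_range=(0.2, 0.4),
    )


def demo_config(seed: int = 7) -> ScenarioConfig:
    """Small clean sequence used for demos and regression pinning."""
    return ScenarioConfig(
        seed=seed,
        n_targets=3,
        n_frames=60,
        frame_size=(320, 240),
        trajectory_kind="random_smooth",
        detection_noise_std=0.4,
    )
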