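"""Four-axis image-based visual servoing for herd following.

The controller turns the confirmed tracks of the current frame into a
velocity command for the vehicle's autopilot:

* **lateral** -- a PID law on the summed horizontal offsets of the tracked
  boxes from the image center, keeping the herd horizontally centered;
* **longitudinal** -- proportional/derivative action on bounding-box heights
  relative to a configured height band (box height is the image's distance
  proxy: too tall means too close), plus optional area-based terms;
* **vertical** -- a proportional law on the altitude error relative to a
  loose altitude band (zero inside the band);
* **yaw rate** -- proportional action on the estimated misalignment between
  the vehicle's forward axis and the perpendicular of the line connecting
  the two outermost tracked objects.

Body frame convention (right-handed): +x right, +y forward, +z up; positive
yaw rate is counterclockwise seen from above.  The final command is rotated
into the world frame by the vehicle heading.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .core import BoundingBox

__all__ = [
    "ServoGains",
    "ServoSignals",
    "VelocityCommand",
    "ServoController",
    "lateral_speed",
    "longitudinal_speed",
    "vertical_speed",
    "estimate_yaw_misalignment",
    "yaw_rate",
    "to_world",
]


@dataclass
class ServoGains:
    """Controller parameters.  Pixel-domain gains map summed pixel errors to
    m/s, so magnitudes are small."""

    kp_x: float = 0.02
    ki_x: float = 2e-5
    kd_x: float = 0.02
    kp_y: float = 0.02
    kd_y: float = 0.01
    b_f: float = 1.0                      # weight on the forward (approach) band term
    kp_z: float = 0.5
    kp_psi: float = 0.1
    height_band: tuple[float, float] = (28.0, 40.0)     # px
    altitude_band: tuple[float, float] = (10.0, 14.0)   # m
    standard_height_per_class: dict = field(
        default_factory=lambda: {"target": 34.0}        # px at reference range
    )
    reference_area: float | None = None   # px^2; None disables area terms
    # lateral-proxy rescaling: 2 tan(hfov/2) cos(tilt); default for a 90 deg
    # horizontal field of view with the camera tilted down 45 deg
    yaw_lateral_scale: float = math.sqrt(2.0)
    integral_limit: float = 1000.0        # anti-windup clamp on Si_x

    def __post_init__(self) -> None:
        if self.height_band[0] >= self.height_band[1]:
            raise ValueError("height_band must satisfy h_min < h_max")
        if self.altitude_band[0] >= self.altitude_band[1]:
            raise ValueError("altitude_band must satisfy z_min < z_max")


@dataclass(frozen=True)
class ServoSignals:
    """Per-frame measured control inputs (pixels unless stated)."""

    sp_x: float = 0.0      # sum of horizontal center offsets from frame center
    si_x: float = 0.0      # accumulated sp_x (pixel-frames)
    sd_x: float = 0.0      # sum of per-object center changes since last frame
    sp_y_a: float = 0.0    # area-based proportional term (dimensionless)
    sd_y_a: float = 0.0    # area-based derivative term
    sp_y_h_b: float = 0.0  # sum of (height - h_max) over too-tall boxes, >= 0
    sp_y_h_f: float = 0.0  # sum of (h_min - height) over too-short boxes, >= 0
    sd_y_h: float = 0.0    # sum of per-object height change rates
    delta_h: float = 0.0   # signed altitude error to the nearest band edge (m)
    psi: float = 0.0       # estimated yaw misalignment (rad)
    delta_t: float = 0.1   # processing interval (s)
    idle: bool = False     # no tracked objects this frame


@dataclass(frozen=True)
class VelocityCommand:
    """World-frame output: translational velocity (m/s) and yaw rate (rad/s)."""

    vx_world: float
    vy_world: float
    vz_world: float
    yaw_rate: float


def lateral_speed(signals: ServoSignals, gains: ServoGains) -> float:
    """Body-frame lateral velocity: PID on summed horizontal offsets."""
    return (
        gains.kp_x * signals.sp_x
        + gains.ki_x * signals.si_x
        + gains.kd_x * signals.sd_x
    )


def longitudinal_speed(signals: ServoSignals, gains: ServoGains) -> float:
    """Body-frame forward velocity from area and height-band terms.

    The too-tall (near) band term and the height-rate term act against the
    forward direction -- the vehicle retreats when boxes grow past the band
    and damps an ongoing approach; the too-short (far) term, weighted by
    ``b_f``, commands approach.
    """
    return (
        gains.kp_y * signals.sp_y_a
        + gains.kd_y * signals.sd_y_a
        - gains.kp_y * signals.sp_y_h_b
        + gains.b_f * gains.kp_y * signals.sp_y_h_f
        - gains.kd_y * signals.sd_y_h
    )


def vertical_speed(signals: ServoSignals, gains: ServoGains) -> float:
    """Proportional altitude-band regulation; zero inside the band."""
    return gains.kp_z * signals.delta_h


def yaw_rate(psi: float, delta_t: float, gains: ServoGains) -> float:
    """Yaw-rate command: misalignment over the processing interval, scaled."""
    if delta_t <= 0:
        raise ValueError("delta_t must be positive")
    return gains.kp_psi * psi / delta_t


def altitude_error(altitude: float, band: tuple[float, float]) -> float:
    """Signed distance to the nearest band edge; zero inside the band."""
    z_min, z_max = band
    if altitude < z_min:
        return z_min - altitude
    if altitude > z_max:
        return z_max - altitude
    return 0.0


def estimate_yaw_misalignment(
    two_outer_objects: tuple[tuple[BoundingBox, str], tuple[BoundingBox, str]],
    frame_size: tuple[float, float],
    gains: ServoGains,
) -> float:
    """Estimate the yaw misalignment from the two outermost tracked objects.

    Uses two image-plane proxies: the normalized height difference
    ``h1/std1 - h2/std2`` (an inverse-range difference, positive when the
    first object is nearer) and the horizontal center separation divided by
    the image width.  The lateral proxy is rescaled by
    ``yaw_lateral_scale`` (the image-width-to-focal-length ratio) so both
    proxies share the inverse-range normalization, and the misalignment is
    their ``atan2``.  Zero for a fronto-parallel pair; swapping the two
    objects flips the sign.
    """
    (box1, cls1), (box2, cls2) = two_outer_objects
    std1 = gains.standard_height_per_class.get(cls1)
    std2 = gains.standard_height_per_class.get(cls2)
    if std1 is None or std2 is None:
        raise KeyError(f"standard heights not configured for {cls1!r}/{cls2!r}")
    c1, c2 = box1.center, box2.center
    if math.hypot(c1[0] - c2[0], c1[1] - c2[1]) < 1e-9:
        raise ValueError("identical object centers: yaw geometry undefined")
    depth_proxy = box1.height / std1 - box2.height / std2
    lateral_proxy = abs(c1[0] - c2[0]) / frame_size[0]
    return math.atan2(depth_proxy, gains.yaw_lateral_scale * lateral_proxy)


def to_world(
    vx_uav: float,
    vy_uav: float,
    vz: float,
    yaw_rate_cmd: float,
    psi_heading: float,
) -> VelocityCommand:
    """Rotate the planar body-frame command into the world frame."""
    c, s = math.cos(psi_heading), math.sin(psi_heading)
    return VelocityCommand(
        vx_world=c * vx_uav - s * vy_uav,
        vy_world=s * vx_uav + c * vy_uav,
        vz_world=vz,
        yaw_rate=yaw_rate_cmd,
    )


class ServoController:
    """Stateful wrapper: accumulates the lateral integral, remembers the
    previous frame's tracked boxes, and emits one command per frame."""

    def __init__(self, gains: ServoGains | None = None):
        self.gains = gains or ServoGains()
        self._si_x = 0.0
        self._prev: dict[int, BoundingBox] = {}

    def reset(self) -> None:
        self._si_x = 0.0
        self._prev = {}

    def compute_signals(
        self,
        tracks_now: list[tuple[int, BoundingBox]],
        frame_size: tuple[float, float],
        delta_t: float,
        altitude: float | None = None,
        psi: float = 0.0,
    ) -> ServoSignals:
        """Measure all control inputs from the current tracked boxes.

        The integral channel resets whenever the tracked-id set changes
        (standard anti-windup hygiene: the summed-offset error is not
        comparable across different herds-in-view) and is clamped.
        """
        if delta_t <= 0:
            raise ValueError("delta_t must be positive")
        gains = self.gains
        if not tracks_now:
            self._prev = {}
            self._si_x = 0.0
            return ServoSignals(delta_t=delta_t, idle=True)

        w_img = frame_size[0]
        now = {tid: box for tid, box in tracks_now}
        if set(now) != set(self._prev):
            self._si_x = 0.0

        sp_x = sum(box.center[0] - w_img / 2.0 for box in now.values())
        sd_x = sum(
            now[tid].center[0] - self._prev[tid].center[0]
            for tid in now
            if tid in self._prev
        )
        self._si_x = float(
            np.clip(self._si_x + sp_x, -gains.integral_limit, gains.integral_limit)
        )

        h_min, h_max = gains.height_band
        sp_y_h_b = sum(b.height - h_max for b in now.values() if b.height > h_max)
        sp_y_h_f = sum(h_min - b.height for b in now.values() if b.height < h_min)
        sd_y_h = sum(
            now[tid].height - self._prev[tid].height
            for tid in now
            if tid in self._prev
        )

        sp_y_a = sd_y_a = 0.0
        if gains.reference_area is not None:
            ref = gains.reference_area
            sp_y_a = sum((ref - b.area) / ref for b in now.values())
            sd_y_a = sum(
                ((ref - now[tid].area) - (ref - self._prev[tid].area)) / ref
                for tid in now
                if tid in self._prev
            )

        delta_h = (
            altitude_error(altitude, gains.altitude_band)
            if altitude is not None
            else 0.0
        )
        self._prev = now
        return ServoSignals(
            sp_x=sp_x, si_x=self._si_x, sd_x=sd_x,
            sp_y_a=sp_y_a, sd_y_a=sd_y_a,
            sp_y_h_b=sp_y_h_b, sp_y_h_f=sp_y_h_f, sd_y_h=sd_y_h,
            delta_h=delta_h, psi=psi, delta_t=delta_t,
        )

    def command(
        self,
        tracks_now: list[tuple[int, BoundingBox]],
        frame_size: tuple[float, float],
        delta_t: float,
        heading: float,
        altitude: float | None = None,
        classes: dict[int, str] | None = None,
    ) -> VelocityCommand:
        """Full control step: signals -> four laws -> world-frame command."""
        psi = 0.0
        if len(tracks_now) >= 2:
            by_x = sorted(tracks_now, key=lambda t: t[1].center[0])
            left, right = by_x[0], by_x[-1]
            cls = classes or {}
            pair = (
                (left[1], cls.get(left[0], "target")),
                (right[1], cls.get(right[0], "target")),
            )
            try:
                psi = estimate_yaw_misalignment(pair, frame_size, self.gains)
            except (ValueError, KeyError):
                psi = 0.0
        signals = self.compute_signals(
            tracks_now, frame_size, delta_t, altitude=altitude, psi=psi
        )
        if signals.idle:
            return VelocityCommand(0.0, 0.0, 0.0, 0.0)
        vx = lateral_speed(signals, self.gains)
        vy = longitudinal_speed(signals, self.gains)
        vz = vertical_speed(signals, self.gains)
        wz = yaw_rate(signals.psi, delta_t, self.gains)
        return to_world(vx, vy, vz, wz, heading)
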