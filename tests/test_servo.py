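"""Control-law fidelity against term-by-term oracles, yaw-estimator geometry,
and closed-loop behavior on the concentric-arc herd."""

import math

import numpy as np
import pytest

from herdtrack.core import BoundingBox
from herdtrack.servo import (
    ServoController,
    ServoGains,
    ServoSignals,
    estimate_yaw_misalignment,
    lateral_speed,
    longitudinal_speed,
    to_world,
    vertical_speed,
    yaw_rate,
)
from herdtrack.simulator import (
    ArcHerdConfig,
    CameraModel,
    UavState,
    perpendicularity_error,
    project_targets,
    run_closed_loop,
)


def random_signals(rng):
    return ServoSignals(
        sp_x=rng.uniform(-300, 300),
        si_x=rng.uniform(-2000, 2000),
        sd_x=rng.uniform(-50, 50),
        sp_y_a=rng.uniform(-2, 2),
        sd_y_a=rng.uniform(-1, 1),
        sp_y_h_b=rng.uniform(0, 30),
        sp_y_h_f=rng.uniform(0, 30),
        sd_y_h=rng.uniform(-10, 10),
        delta_h=rng.uniform(-3, 3),
        psi=rng.uniform(-1, 1),
        delta_t=rng.uniform(0.02, 0.5),
    )


class TestLaws:
    def test_equilibrium_zero(self):
        g = ServoGains()
        s = ServoSignals()
        assert lateral_speed(s, g) == 0.0
        assert longitudinal_speed(s, g) == 0.0
        assert vertical_speed(s, g) == 0.0
        assert yaw_rate(0.0, 0.1, g) == 0.0

    def test_single_term_examples(self):
        g = ServoGains(kp_x=0.01, ki_x=0.0, kd_x=0.0)
        assert lateral_speed(ServoSignals(sp_x=50), g) == pytest.approx(0.5)
        g2 = ServoGains(kp_y=0.02, kd_y=0.0)
        assert longitudinal_speed(ServoSignals(sp_y_h_b=10), g2) == pytest.approx(-0.2)
        g3 = ServoGains(kp_z=0.5)
        assert vertical_speed(ServoSignals(delta_h=-2.0), g3) == pytest.approx(-1.0)
        assert yaw_rate(0.3, 0.1, ServoGains(kp_psi=0.1)) == pytest.approx(0.3)

    def test_laws_match_formula_oracle(self):
        """Each law equals its explicit term-by-term formula to 1e-12 over
        random signals and gains."""
        rng = np.random.default_rng(11)
        for _ in range(200):
            g = ServoGains(
                kp_x=rng.uniform(-1, 1), ki_x=rng.uniform(-1, 1),
                kd_x=rng.uniform(-1, 1), kp_y=rng.uniform(-1, 1),
                kd_y=rng.uniform(-1, 1), b_f=rng.uniform(-2, 2),
                kp_z=rng.uniform(-1, 1), kp_psi=rng.uniform(-1, 1),
            )
            s = random_signals(rng)
            assert lateral_speed(s, g) == pytest.approx(
                g.kp_x * s.sp_x + g.ki_x * s.si_x + g.kd_x * s.sd_x, abs=1e-12
            )
            assert longitudinal_speed(s, g) == pytest.approx(
                g.kp_y * s.sp_y_a + g.kd_y * s.sd_y_a - g.kp_y * s.sp_y_h_b
                + g.b_f * g.kp_y * s.sp_y_h_f - g.kd_y * s.sd_y_h,
                abs=1e-12,
            )
            assert vertical_speed(s, g) == pytest.approx(g.kp_z * s.delta_h, abs=1e-12)
            assert yaw_rate(s.psi, s.delta_t, g) == pytest.approx(
                g.kp_psi * s.psi / s.delta_t, abs=1e-12
            )

    def test_laws_linear_in_gains(self):
        rng = np.random.default_rng(4)
        s = random_signals(rng)
        g1 = ServoGains(kp_x=0.01, ki_x=0.001, kd_x=0.005)
        g2 = ServoGains(kp_x=0.02, ki_x=0.002, kd_x=0.010)
        assert lateral_speed(s, g2) == pytest.approx(2 * lateral_speed(s, g1))

    def test_yaw_rate_delta_t_scaling_and_guard(self):
        g = ServoGains(kp_psi=0.2)
        assert yaw_rate(0.4, 0.2, g) == pytest.approx(yaw_rate(0.4, 0.1, g) / 2)
        with pytest.raises(ValueError):
            yaw_rate(0.1, 0.0, g)


class TestWorldTransform:
    def test_identity_at_zero_heading(self):
        cmd = to_world(1.0, 2.0, 0.5, 0.1, 0.0)
        assert (cmd.vx_world, cmd.vy_world) == (1.0, 2.0)
        assert cmd.vz_world == 0.5 and cmd.yaw_rate == 0.1

    def test_quarter_turn(self):
        cmd = to_world(1.0, 0.0, 0.0, 0.0, math.pi / 2)
        assert cmd.vx_world == pytest.approx(0.0, abs=1e-12)
        assert cmd.vy_world == pytest.approx(1.0)

    def test_norm_preserved_100_headings(self):
        rng = np.random.default_rng(2)
        for _ in range(100):
            vx, vy = rng.uniform(-3, 3, size=2)
            psi = rng.uniform(-2 * math.pi, 2 * math.pi)
            cmd = to_world(vx, vy, 0.0, 0.0, psi)
            assert math.hypot(cmd.vx_world, cmd.vy_world) == pytest.approx(
                math.hypot(vx, vy), abs=1e-12
            )


class TestSignals:
    def test_centered_targets_zero_proportional(self):
        ctl = ServoController()
        tracks = [
            (1, BoundingBox(320 - 15, 200, 30, 30)),
            (2, BoundingBox(320 - 15, 300, 30, 30)),
        ]
        s = ctl.compute_signals(tracks, (640, 480), 0.1)
        assert s.sp_x == pytest.approx(0.0)
        assert s.sd_x == 0.0

    def test_offset_and_band_arithmetic(self):
        gains = ServoGains(height_band=(28, 40))
        ctl = ServoController(gains)
        tracks = [(1, BoundingBox(320 + 50 - 15, 200, 30, 50))]  # h over band by 10
        s = ctl.compute_signals(tracks, (640, 480), 0.1)
        assert s.sp_x == pytest.approx(50.0)
        assert s.sp_y_h_b == pytest.approx(10.0)
        assert s.sp_y_h_f == 0.0

    def test_idle_on_empty(self):
        ctl = ServoController()
        s = ctl.compute_signals([], (640, 480), 0.1)
        assert s.idle and s.sp_x == 0.0

    def test_integral_resets_on_id_change(self):
        ctl = ServoController()
        box = BoundingBox(400, 200, 30, 30)
        ctl.compute_signals([(1, box)], (640, 480), 0.1)
        s = ctl.compute_signals([(1, box)], (640, 480), 0.1)
        assert s.si_x != 0.0
        s2 = ctl.compute_signals([(2, box)], (640, 480), 0.1)
        assert s2.si_x == pytest.approx(s2.sp_x)  # freshly accumulated


class TestYawEstimator:
    def test_symmetric_pair_zero(self):
        g = ServoGains(standard_height_per_class={"target": 30.0})
        pair = (
            (BoundingBox(100, 200, 45, 30), "target"),
            (BoundingBox(500, 200, 45, 30), "target"),
        )
        assert estimate_yaw_misalignment(pair, (640, 480), g) == pytest.approx(0.0)

    def test_antisymmetry_under_swap(self):
        g = ServoGains(standard_height_per_class={"target": 30.0})
        near = (BoundingBox(100, 200, 48, 33), "target")
        far = (BoundingBox(500, 200, 42, 27), "target")
        psi1 = estimate_yaw_misalignment((near, far), (640, 480), g)
        psi2 = estimate_yaw_misalignment((far, near), (640, 480), g)
        assert psi1 > 0
        assert psi2 == pytest.approx(-psi1)

    def test_identical_centers_rejected(self):
        g = ServoGains(standard_height_per_class={"target": 30.0})
        box = BoundingBox(100, 200, 45, 30)
        with pytest.raises(ValueError):
            estimate_yaw_misalignment(((box, "target"), (box, "target")), (640, 480), g)

    def test_matches_projected_geometry(self):
        """On pinhole-projected target pairs the estimate agrees with the
        true yaw misalignment within 0.05 rad."""
        camera = CameraModel()
        f = camera.focal
        z_ref = 15.0
        std_h = f * 1.6 / z_ref
        gains = ServoGains(standard_height_per_class={"target": std_h})
        for true_err in (-0.25, -0.1, 0.0, 0.1, 0.25):
            uav = UavState(position=np.array([0.0, -z_ref / math.sqrt(2), 10.6066]))
            # two targets on a line rotated by true_err around their midpoint
            mid = np.array([0.0, 0.0])
            half = 3.0
            d = np.array([math.cos(true_err), math.sin(true_err)]) * half
            targets = [
                (1, np.array([*(mid - d), 0.8])),
                (2, np.array([*(mid + d), 0.8])),
            ]
            projected = project_targets(uav, targets, camera)
            assert all(ok for _, _, ok in projected)
            by_x = sorted(projected, key=lambda p: p[1].center[0])
            pair = ((by_x[0][1], "target"), (by_x[-1][1], "target"))
            est = estimate_yaw_misalignment(pair, camera.frame_size, gains)
            assert abs(abs(est) - abs(true_err)) < 0.05


class TestClosedLoop:
    def test_centered_static_targets_zero_command(self):
        """A symmetric, in-band herd with the vehicle inside its altitude
        band is an equilibrium: every command component is zero."""
        camera = CameraModel()
        gains = ServoGains(altitude_band=(10, 14))
        ctl = ServoController(gains)
        h_mid = sum(gains.height_band) / 2
        w = h_mid * 1.5
        cx = camera.frame_size[0] / 2
        tracks = [
            (1, BoundingBox(cx - 100 - w / 2, 200, w, h_mid)),
            (2, BoundingBox(cx + 100 - w / 2, 200, w, h_mid)),
        ]
        for _ in range(3):
            cmd = ctl.command(tracks, camera.frame_size, 0.1, heading=0.0, altitude=12.0)
        assert cmd.vx_world == pytest.approx(0.0, abs=1e-9)
        assert cmd.vy_world == pytest.approx(0.0, abs=1e-9)
        assert cmd.vz_world == 0.0
        assert cmd.yaw_rate == pytest.approx(0.0, abs=1e-9)

    def test_lateral_offset_decays(self):
        """A laterally offset static herd is recentered: the pixel offset
        decays monotonically (after the first transient steps)."""
        from herdtrack.simulator import uav_step

        camera = CameraModel()
        gains = ServoGains()
        ctl = ServoController(gains)
        target = np.array([6.0, 12.0, 0.8])  # offset right of the camera axis
        uav = UavState(position=np.array([0.0, 0.0, 12.0]))
        offsets = []
        for _ in range(250):
            proj = project_targets(uav, [(1, target)], camera)
            (tid, box, ok) = proj[0]
            assert ok
            offsets.append(abs(box.center[0] - camera.frame_size[0] / 2))
            cmd = ctl.command([(1, box)], camera.frame_size, 0.1,
                              heading=uav.heading, altitude=float(uav.position[2]))
            uav = uav_step(uav, cmd, 0.1, response_time=0.2)
        assert offsets[-1] < 2.0
        tail = offsets[30:]
        assert all(b <= a + 0.5 for a, b in zip(tail, tail[1:]))

    def test_perpendicular_alignment_steady_state(self):
        """Closed loop on the concentric-arc herd: after the transient the
        forward axis stays within 0.3 rad of perpendicular to the
        inter-target line."""
        log = run_closed_loop(ArcHerdConfig(duration_s=60.0))
        tail = log[log["t"] > 30.0]
        assert (tail["n_visible"] == 2).all()
        assert tail["perp_error"].max() < 0.3
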