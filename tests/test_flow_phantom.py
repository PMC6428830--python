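import numpy as np
import pytest

from mmtrack import (
    FlowField,
    GeometryError,
    InvalidArgumentError,
    MagneticSphere,
    PhantomGeometry,
    local_kinematics,
    local_lumen,
    moment_from_diameter,
    simulate_trajectory,
)
from mmtrack.flow_phantom import read_trajectory, write_trajectory


class TestFlowField:
    def test_poiseuille_consistency_enforced(self):
        with pytest.raises(InvalidArgumentError, match="inconsistent"):
            FlowField(0.40, 2e-6, 30e-6 / 60.0, 1.5e-3)

    def test_centerline_is_twice_mean(self, reference_flow):
        v_avg = reference_flow.flow_rate / (np.pi * (1.5e-3 / 2) ** 2)
        assert reference_flow.centerline_velocity == pytest.approx(2 * v_avg, rel=1e-12)


class TestLocalLumen:
    def test_upstream_unchanged(self):
        g = PhantomGeometry(reduction=0.5)
        d, point, tangent = local_lumen(g, -0.06)
        assert d == pytest.approx(1.5e-3)
        assert np.allclose(point, [-0.06, 0, 0])
        assert np.allclose(tangent, [1, 0, 0])

    def test_constriction_center_half_reduction(self):
        g = PhantomGeometry(reduction=0.5)
        d, _, _ = local_lumen(g, g.constriction_center_x)
        assert d == pytest.approx(0.75e-3, rel=1e-12)

    def test_taper_midpoint(self):
        g = PhantomGeometry(reduction=0.4, taper_length=1e-3)
        x_mid = g.constriction_center_x + g.constriction_length / 2 + 0.5e-3
        d, _, _ = local_lumen(g, x_mid)
        assert d == pytest.approx(1.5e-3 * (1 - 0.2), rel=1e-12)

    def test_bend_centerline_and_tangent(self):
        g = PhantomGeometry(bend_radius=0.02, bend_angle=np.pi / 2)
        x_end = g.x_max
        d, point, tangent = local_lumen(g, x_end)
        assert np.allclose(point, [g.straight_length / 2 + 0.02, 0.02, 0], atol=1e-12)
        assert np.allclose(tangent, [0, 1, 0], atol=1e-12)

    def test_out_of_range(self):
        g = PhantomGeometry()
        with pytest.raises(InvalidArgumentError):
            local_lumen(g, g.x_min - 0.01)


class TestLocalKinematics:
    def test_centerline_no_shear(self, flow_056):
        g = PhantomGeometry(reduction=0.0)
        speed, f = local_kinematics(g, flow_056, 0.0, -0.05, lag=1.0)
        assert speed == pytest.approx(0.56)
        assert f == 0.0

    def test_half_radius_values(self, flow_056):
        """At half the tube radius, Poiseuille gives 0.42 m/s and 59.4 Hz."""
        g = PhantomGeometry(reduction=0.0)
        speed, f = local_kinematics(g, flow_056, 0.5, -0.05, lag=1.0)
        assert speed == pytest.approx(0.42, rel=1e-9)
        assert f == pytest.approx(59.4, rel=2e-3)
        # cross-check: the closed form v = v0 - (pi f d)^2 / v0
        assert speed == pytest.approx(0.56 - (np.pi * f * 1.5e-3) ** 2 / 0.56,
                                      rel=1e-12)

    def test_constriction_scaling(self, flow_056):
        """A 50% reduction quadruples the speed and octuples the frequency."""
        g0 = PhantomGeometry(reduction=0.0)
        g5 = PhantomGeometry(reduction=0.5)
        s0, f0 = local_kinematics(g0, flow_056, 0.3, 0.0, lag=1.0)
        s5, f5 = local_kinematics(g5, flow_056, 0.3, 0.0, lag=1.0)
        assert s5 / s0 == pytest.approx(4.0, rel=1e-12)
        assert f5 / f0 == pytest.approx(8.0, rel=1e-12)

    def test_invalid_relative_radius(self, flow_056):
        with pytest.raises(InvalidArgumentError):
            local_kinematics(PhantomGeometry(), flow_056, 1.0, 0.0)


class TestMomentFromDiameter:
    def test_volume_ratio(self):
        """A 5.7 um sphere at 0.9 pA m^2 / um^3 carries 87.3 pA m^2."""
        assert moment_from_diameter(5.7e-6, 0.9) * 1e12 == pytest.approx(87.3, rel=1e-3)

    def test_cubic_scaling(self):
        assert moment_from_diameter(2e-5) / moment_from_diameter(1e-5) == pytest.approx(8.0)


class TestSimulateTrajectory:
    def test_on_axis_constant_speed_no_rotation(self, flow_056, mm1):
        g = PhantomGeometry(reduction=0.0)
        states = simulate_trajectory(g, flow_056, mm1, 0.05, 750.0, lag=0.8,
                                     initial_relative_radius=0.0)
        v = np.array([s.true_velocity for s in states])
        f = np.array([s.true_rotation_frequency for s in states])
        th = np.array([s.theta for s in states])
        np.testing.assert_allclose(v, 0.8 * 0.56, rtol=1e-12)
        np.testing.assert_allclose(f, 0.0, atol=1e-15)
        assert np.ptp(th) < 1e-12

    def test_vf_closed_form_straight_tube(self, flow_056, mm1):
        """Every straight-tube state at lag 1 satisfies
        v = v0 - (pi f d)^2 / v0 to 1e-9 relative."""
        g = PhantomGeometry(reduction=0.3, straight_length=0.2)
        states = simulate_trajectory(g, flow_056, mm1, 0.2, 750.0, lag=1.0,
                                     initial_relative_radius=0.5, start_x=-0.09)
        for s in states:
            if s.position[0] < g.straight_length / 2:
                v_theory = 0.56 - (np.pi * s.true_rotation_frequency * 1.5e-3) ** 2 / 0.56
                # at the local scale: use local diameter for constricted states
                v_local = (0.56 * (1.5e-3 / s.local_diameter) ** 2)
                rr = s.true_rotation_frequency * 2 * np.pi * (s.local_diameter / 2) / v_local
                expected = v_local * (1 - rr**2)
                assert s.true_velocity == pytest.approx(expected, rel=1e-9)
                if s.local_diameter == pytest.approx(1.5e-3, rel=1e-12):
                    assert s.true_velocity == pytest.approx(v_theory, rel=1e-9)

    def test_mass_continuity_along_path(self, flow_056, mm1):
        """Sphere speed scales exactly as (d_tube / d_local)^2."""
        g = PhantomGeometry(reduction=0.4)
        states = simulate_trajectory(g, flow_056, mm1, 0.3, 750.0, lag=1.0,
                                     initial_relative_radius=0.3, start_x=-0.03)
        base = [s for s in states if s.local_diameter == pytest.approx(1.5e-3, rel=1e-12)]
        for s in states:
            if s.position[0] < g.straight_length / 2:
                ratio = (1.5e-3 / s.local_diameter) ** 2
                assert s.true_velocity == pytest.approx(
                    base[0].true_velocity * ratio, rel=1e-9)

    def test_constriction_rise_and_return(self, flow_056, mm1):
        """Speed and frequency rise inside the constricted span and return."""
        g = PhantomGeometry(reduction=0.5, straight_length=0.12)
        states = simulate_trajectory(g, flow_056, mm1, 0.4, 750.0, lag=0.65,
                                     initial_relative_radius=0.5, start_x=-0.05)
        x = np.array([s.position[0] for s in states])
        v = np.array([s.true_velocity for s in states])
        f = np.array([s.true_rotation_frequency for s in states])
        inside = np.abs(x) < 0.004
        before = x < -0.007
        after = (x > 0.007) & (x < 0.05)
        assert v[inside].min() > 3.9 * v[before].mean()
        assert f[inside].min() > 7.8 * f[before].mean()
        assert v[after].mean() == pytest.approx(v[before].mean(), rel=1e-6)

    def test_moment_direction_unit_norm(self, flow_056, mm1):
        g = PhantomGeometry(reduction=0.2)
        states = simulate_trajectory(g, flow_056, mm1, 0.1, 750.0,
                                     initial_relative_radius=0.5, start_x=-0.02)
        for s in states[::10]:
            u = np.array([
                np.sin(s.theta) * np.cos(s.phi),
                np.sin(s.theta) * np.sin(s.phi),
                np.cos(s.theta),
            ])
            assert np.linalg.norm(u) == pytest.approx(1.0, abs=1e-12)

    def test_position_inside_lumen(self, flow_056, mm1):
        g = PhantomGeometry(reduction=0.5)
        states = simulate_trajectory(
            g, flow_056, mm1, 0.3, 750.0, initial_relative_radius=0.7,
            start_x=-0.03, oscillation={"amplitude_fraction": 0.1, "harmonic": 2},
        )
        for s in states:
            _, center, _ = local_lumen(g, min(max(s.position[0], g.x_min), g.x_max))
            offset = np.linalg.norm(s.position - center)
            if s.position[0] < g.straight_length / 2:  # straight section only
                assert offset <= s.local_diameter / 2 - mm1.radius + 1e-12

    def test_bend_drift_reduces_rotation(self, flow_056, mm1):
        g = PhantomGeometry(reduction=0.0, straight_length=0.04,
                            bend_radius=0.02, bend_angle=np.pi)
        states = simulate_trajectory(g, flow_056, mm1, 0.4, 750.0, lag=1.0,
                                     initial_relative_radius=0.5,
                                     bend_drift_rate=8.0)
        f = np.array([s.true_rotation_frequency for s in states])
        v = np.array([s.true_velocity for s in states])
        assert f[-1] < 0.5 * f[0]
        assert v[-1] > v[0]

    def test_sphere_too_large_for_constriction(self, flow_056):
        big = MagneticSphere(diameter=0.8e-3, moment_magnitude=1e-8)
        with pytest.raises(GeometryError):
            simulate_trajectory(PhantomGeometry(reduction=0.5), flow_056, big,
                                0.1, 750.0)

    def test_determinism(self, flow_056, mm1):
        g = PhantomGeometry(reduction=0.3)
        kw = dict(duration=0.1, sample_rate=750.0, initial_relative_radius=0.5,
                  start_x=-0.02)
        s1 = simulate_trajectory(g, flow_056, mm1, **kw)
        s2 = simulate_trajectory(g, flow_056, mm1, **kw)
        np.testing.assert_array_equal(
            np.array([s.position for s in s1]), np.array([s.position for s in s2]))

    def test_trajectory_round_trip(self, tmp_path, flow_056, mm1):
        g = PhantomGeometry()
        states = simulate_trajectory(g, flow_056, mm1, 0.02, 750.0, start_x=-0.01)
        path = tmp_path / "traj.csv"
        write_trajectory(states, path, config={"a": 1}, seed=3)
        back = read_trajectory(path)
        assert len(back) == len(states)
        np.testing.assert_allclose(
            np.array([s.position for s in back]),
            np.array([s.position for s in states]), rtol=1e-8)
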