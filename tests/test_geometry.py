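"""Arch height, angles, segment kinematics, and load geometry."""

import numpy as np
import pytest

from archstiff.errors import BadMeta, DegenerateFrame, TooShort
from archstiff.geometry import (arch_height, body_load_direction, load_geometry,
                                mtpj_angle, nnht, segment_states)
from archstiff.phases import StancePhases
from archstiff.preprocess import PlanarTrial


class TestArchHeight:
    def test_simple_triangle(self):
        h, d = arch_height([0.0, 10.0], [-50.0, 0.0], [50.0, 0.0])
        assert h == pytest.approx(10.0)
        np.testing.assert_allclose(d, [0.0, 1.0])

    def test_nav_on_line(self):
        h, _ = arch_height([5.0, 0.0], [-50.0, 0.0], [50.0, 0.0])
        assert h == pytest.approx(0.0, abs=1e-12)

    def test_cross_product_oracle(self, rng):
        """1000 random triangles: h equals |cross| / base length."""
        nav = rng.uniform(-100, 100, size=(1000, 2))
        cal = rng.uniform(-100, 100, size=(1000, 2))
        met1 = cal + rng.uniform(5, 200, size=(1000, 1)) * _unit(rng, 1000)
        h, _ = arch_height(nav, cal, met1)
        b = met1 - cal
        r = nav - cal
        expected = np.abs(b[:, 0] * r[:, 1] - b[:, 1] * r[:, 0]) / np.linalg.norm(b, axis=1)
        np.testing.assert_allclose(h, expected, atol=1e-9)

    def test_rigid_motion_invariance(self, rng):
        nav, cal, met1 = (rng.uniform(-50, 50, size=2) for _ in range(3))
        met1 = cal + np.array([80.0, 10.0])
        h0, _ = arch_height(nav, cal, met1)
        ang = 1.1
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        t = np.array([17.0, -260.0])
        h1, _ = arch_height(rot @ nav + t, rot @ cal + t, rot @ met1 + t)
        assert h1 == pytest.approx(h0, abs=1e-9)

    def test_coincident_base_rejected(self):
        with pytest.raises(DegenerateFrame):
            arch_height([0.0, 10.0], [1.0, 1.0], [1.0, 1.0])


class TestNNHt:
    def test_reference_ratio(self):
        assert nnht(31.9, 197.0) == pytest.approx(0.1619, abs=5e-5)

    def test_zero_height(self):
        assert nnht(0.0, 180.0) == 0.0

    def test_bad_length(self):
        with pytest.raises(BadMeta):
            nnht(30.0, 0.0)

    def test_generator_static_value(self, clean_result):
        assert clean_result.summary.static_nnht == pytest.approx(0.162, abs=1e-6)


class TestMTPJAngle:
    def test_collinear_is_zero(self):
        a = mtpj_angle([50.0, 0.0], [80.0, 0.0], [-50.0, 0.0])
        assert a == pytest.approx(0.0, abs=1e-12)

    @pytest.mark.parametrize("deg", [30.0, 12.5, 75.0])
    def test_rotation_construction(self, deg):
        """HLX rotated dorsally about MET1 from collinear reads as +deg."""
        met1 = np.array([50.0, 0.0])
        hlx0 = np.array([80.0, 0.0])
        ang = np.radians(deg)
        rot = np.array([[np.cos(ang), -np.sin(ang)], [np.sin(ang), np.cos(ang)]])
        hlx = met1 + rot @ (hlx0 - met1)
        assert mtpj_angle(met1, hlx, [-50.0, 0.0]) == pytest.approx(deg)

    def test_mirror_antisymmetry(self, rng):
        for _ in range(20):
            cal = np.array([-60.0, 5.0])
            met1 = np.array([40.0, -3.0])
            hlx = met1 + rng.uniform(5, 40, size=2)
            a = mtpj_angle(met1, hlx, cal)
            # reflect HLX across the CAL->MET1 line
            u = (met1 - cal) / np.linalg.norm(met1 - cal)
            r = hlx - met1
            hlx_m = met1 + 2 * np.dot(r, u) * u - r
            b = mtpj_angle(met1, hlx_m, cal)
            assert b == pytest.approx(-a, abs=1e-9)


class TestBodyLoadDirection:
    def test_vertical_shank(self):
        assert body_load_direction([0.0, 70.0], [0.0, 400.0]) == pytest.approx(np.pi / 2)

    def test_forward_tilt(self):
        ang = np.radians(10.0)
        shk = np.array([0.0, 70.0]) + 330.0 * np.array([np.sin(ang), np.cos(ang)])
        got = body_load_direction([0.0, 70.0], shk)
        assert got == pytest.approx(np.pi / 2 - ang)

    def test_atan2_oracle(self, rng):
        for _ in range(50):
            ank = rng.uniform(-100, 100, size=2)
            shk = ank + rng.uniform(50, 400) * _unit(rng, 1)[0]
            v = shk - ank
            assert body_load_direction(ank, shk) == pytest.approx(
                np.arctan2(v[1], v[0]))


def _unit(rng, n):
    a = rng.uniform(0, 2 * np.pi, size=n)
    return np.stack([np.cos(a), np.sin(a)], axis=1)


def _planar_from(markers, rate=100.0):
    return PlanarTrial(markers=markers, rate=rate)


class TestSegmentStates:
    def test_stationary_zero_acceleration(self):
        n = 20
        m = {k: np.tile(v, (n, 1)) for k, v in {
            "CAL": [0.0, 15.0], "NAV": [90.0, 45.0], "MET1": [197.0, 18.0]}.items()}
        rear, fore = segment_states(_planar_from(m))
        assert np.allclose(rear.com_acc, 0) and np.allclose(fore.com_acc, 0)
        assert np.allclose(rear.theta_acc, 0)

    def test_uniform_acceleration_recovered(self):
        """CoM following x = 0.5 a t^2 with a = 2 m/s^2 reads back a."""
        rate, n, a = 100.0, 50, 2.0
        t = np.arange(n) / rate
        x_mm = 0.5 * a * t ** 2 * 1e3
        m = {"CAL": np.stack([x_mm, np.full(n, 15.0)], axis=1),
             "NAV": np.stack([x_mm + 90, np.full(n, 45.0)], axis=1),
             "MET1": np.stack([x_mm + 197, np.full(n, 18.0)], axis=1)}
        rear, _ = segment_states(_planar_from(m, rate))
        np.testing.assert_allclose(rear.com_acc[2:-2, 0], a, atol=1e-6)

    def test_constant_rotation(self):
        """Rigid rotation at constant omega: zero angular acceleration and
        centripetal CoM acceleration omega^2 r toward the pivot."""
        rate, n, omega = 100.0, 80, 3.0
        t = np.arange(n) / rate
        ang = omega * t
        r_cal, r_nav, r_met = 30.0, 90.0, 150.0
        def circ(r):
            return np.stack([r * np.cos(ang), r * np.sin(ang)], axis=1)
        m = {"CAL": circ(r_cal), "NAV": circ(r_nav), "MET1": circ(r_met)}
        rear, _ = segment_states(_planar_from(m, rate))
        np.testing.assert_allclose(rear.theta_acc[3:-3], 0.0, atol=1e-6)
        r_com_m = (r_cal + r_nav) / 2 * 1e-3
        a_mag = np.linalg.norm(rear.com_acc[3:-3], axis=1)
        np.testing.assert_allclose(a_mag, omega ** 2 * r_com_m, rtol=1e-3)

    def test_too_few_frames(self):
        m = {k: np.zeros((3, 2)) for k in ("CAL", "NAV", "MET1")}
        m["MET1"] += [100.0, 0.0]
        with pytest.raises(TooShort):
            segment_states(_planar_from(m))


class TestLoadGeometry:
    def _planar(self, ank, shk, n=30):
        m = {"CAL": np.tile([10.0, 15.0], (n, 1)),
             "NAV": np.tile([50.0, 30.0], (n, 1)),
             "MET1": np.tile([200.0, 18.0], (n, 1)),
             "ANK": np.tile(ank, (n, 1)), "SHK": np.tile(shk, (n, 1))}
        return _planar_from(m)

    def test_arch_point_relative_to_heel_origin(self):
        planar = self._planar([10.0, 70.0], [10.0, 400.0])
        ph = StancePhases(2, 8, 18, 28)
        arch_rear, arch_fore, _, _ = load_geometry(planar, ph)
        np.testing.assert_allclose(arch_rear[5], [40.0, 30.0])   # NAV - (10, 0)
        np.testing.assert_allclose(arch_fore[5], [-150.0, 30.0])  # NAV - (200, 0)

    def test_vertical_load_through_origin_has_zero_arm(self):
        planar = self._planar([10.0, 70.0], [10.0, 400.0])  # ANK above CAL(x=10)
        ph = StancePhases(2, 8, 18, 28)
        _, _, l_b, theta_b = load_geometry(planar, ph)
        assert theta_b[0] == pytest.approx(np.pi / 2)
        np.testing.assert_allclose(l_b, 0.0, atol=1e-9)

    def test_line_point_distance_oracle(self, rng):
        for _ in range(30):
            ank = np.array([rng.uniform(-50, 150), rng.uniform(40, 120)])
            ang = rng.uniform(np.pi / 4, 3 * np.pi / 4)
            shk = ank + 330.0 * np.array([np.cos(ang), np.sin(ang)])
            planar = self._planar(ank, shk)
            ph = StancePhases(2, 8, 18, 28)
            _, _, l_b, theta_b = load_geometry(planar, ph)
            # oracle: signed horizontal offset of the ground intercept of a
            # line through ANK with direction theta_b, relative to CAL x
            direction = np.array([np.cos(ang), np.sin(ang)])
            tpar = -ank[1] / direction[1]
            x_int = ank[0] + tpar * direction[0]
            assert l_b[0] == pytest.approx(x_int - 10.0, abs=1e-9)
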