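"""Free-body equations, arch load, and the phase-dispatched series."""

import numpy as np
import pytest

from archstiff.dynamics import (PATensionCurve, SegmentInertia, arch_load,
                                heel_contact_dynamics, pa_tension,
                                plantar_contact_load, pushoff_dynamics)
from archstiff.errors import BadPhaseTime
from archstiff.phases import PC

STATIC = SegmentInertia(m_rear=0.55, m_fore=0.36, j_rear=2e-3, j_fore=1.5e-3)
NO_ACC = (np.zeros(2), 0.0)


def random_hc_inputs(rng, n):
    return dict(
        ff1=rng.uniform(-500, 500, n),
        fgr1=rng.uniform(0, 1500, n),
        theta_b=rng.uniform(0.3, np.pi - 0.3, n),
        l_b=rng.uniform(-80, 80, n),
        fpa=rng.uniform(0, 700, n),
        arch_point=rng.uniform(-100, 100, (n, 2)),
        rear_acc=rng.uniform(-5, 5, (n, 2)),
        rear_theta_acc=rng.uniform(-50, 50, n),
    )


class TestPATension:
    def test_zero_curve(self):
        curve = PATensionCurve.zero()
        assert pa_tension(50.0, curve, 700.0) == 0.0

    def test_linear_midpoint(self):
        curve = PATensionCurve(knots=np.array([[0.0, 0.0], [100.0, 1.0]]))
        assert pa_tension(50.0, curve, 700.0) == pytest.approx(350.0)

    def test_matches_interp_oracle(self, rng):
        pcts = np.sort(rng.uniform(0, 100, 12))
        pcts[0], pcts[-1] = 0.0, 100.0
        fracs = rng.uniform(0, 1.5, 12)
        curve = PATensionCurve(knots=np.stack([pcts, fracs], axis=1))
        q = rng.uniform(0, 100, 200)
        expected = np.array([np.interp(x, pcts, fracs) for x in q]) * 650.0
        np.testing.assert_allclose(pa_tension(q, curve, 650.0), expected, atol=1e-9)

    def test_out_of_range(self):
        with pytest.raises(BadPhaseTime):
            pa_tension(101.0, PATensionCurve(), 700.0)

    def test_bad_knots_rejected(self):
        with pytest.raises(BadPhaseTime):
            PATensionCurve(knots=np.array([[0.0, 0.0], [0.0, 1.0]]))


class TestHeelContact:
    def test_static_vertical_load(self):
        fax, fay, ma = heel_contact_dynamics(
            ff1=0.0, fgr1=600.0, theta_b=np.pi / 2, l_b=20.0, fpa=0.0,
            arch_point=np.array([40.0, 30.0]), rear_acc=np.zeros(2),
            rear_theta_acc=0.0, inertia=STATIC)
        assert fax == pytest.approx(0.0, abs=1e-12)
        assert fay == pytest.approx(0.0, abs=1e-12)
        assert ma == pytest.approx(12000.0)

    def test_pa_tension_linearity(self):
        base = heel_contact_dynamics(0.0, 600.0, np.pi / 2, 20.0, 0.0,
                                     np.array([40.0, 30.0]), np.zeros(2), 0.0, STATIC)
        with_pa = heel_contact_dynamics(0.0, 600.0, np.pi / 2, 20.0, 100.0,
                                        np.array([40.0, 30.0]), np.zeros(2), 0.0, STATIC)
        assert with_pa[0] - base[0] == pytest.approx(100.0)
        assert with_pa[1] == pytest.approx(base[1])
        # MA changes by -FAx_delta * yA
        assert with_pa[2] - base[2] == pytest.approx(-100.0 * 30.0)

    def test_newton_residual(self, rng):
        """Back-substitution into the assembled heel-contact equations of
        motion reproduces both force rows and the moment row to <= 1e-9."""
        inp = random_hc_inputs(rng, 1000)
        fax, fay, ma = heel_contact_dynamics(
            inp["ff1"], inp["fgr1"], inp["theta_b"], inp["l_b"], inp["fpa"],
            inp["arch_point"], inp["rear_acc"], inp["rear_theta_acc"], STATIC)
        fbw = inp["fgr1"]  # model: body load equals rearfoot vertical GRF
        rx = (inp["ff1"] + inp["fpa"] - fbw * np.cos(inp["theta_b"]) - fax
              - STATIC.m_rear * inp["rear_acc"][:, 0])
        ry = (inp["fgr1"] - fbw * np.sin(inp["theta_b"]) - fay
              - STATIC.m_rear * inp["rear_acc"][:, 1])
        rm = (fbw * inp["l_b"] + fay * inp["arch_point"][:, 0]
              - fax * inp["arch_point"][:, 1] - ma
              - STATIC.j_rear * inp["rear_theta_acc"] * 1e3)
        scale = np.abs(fbw * inp["l_b"]) + np.abs(fax) + np.abs(fay) + 1.0
        assert np.max(np.abs(rx)) <= 1e-9 * np.max(scale)
        assert np.max(np.abs(ry)) <= 1e-9 * np.max(scale)
        assert np.max(np.abs(rm) / scale) <= 1e-9


class TestPlantarContact:
    def test_three_four_five(self):
        assert plantar_contact_load(300.0, 0.0, 400.0, 0.0) == pytest.approx(500.0)

    def test_zeros(self):
        assert plantar_contact_load(0.0, 0.0, 0.0, 0.0) == 0.0

    def test_random_oracle(self, rng):
        q = rng.uniform(-800, 800, (1000, 4))
        got = plantar_contact_load(q[:, 0], q[:, 1], q[:, 2], q[:, 3])
        np.testing.assert_allclose(got, np.sqrt((q ** 2).sum(axis=1)), atol=1e-9)


class TestPushOff:
    def test_static_example(self):
        fax, fay, ma = pushoff_dynamics(
            ff2=0.0, fgr2=500.0, fpa=0.0, arch_point_fore=np.array([-80.0, 30.0]),
            fore_acc=np.zeros(2), fore_theta_acc=0.0, inertia=STATIC)
        assert fax == pytest.approx(0.0, abs=1e-12)
        assert fay == pytest.approx(500.0)
        assert ma == pytest.approx(-40000.0)

    def test_pa_increases_fax_exactly(self):
        a = pushoff_dynamics(0.0, 500.0, 0.0, np.array([-80.0, 30.0]),
                             np.zeros(2), 0.0, STATIC)
        b = pushoff_dynamics(0.0, 500.0, 200.0, np.array([-80.0, 30.0]),
                             np.zeros(2), 0.0, STATIC)
        assert b[0] - a[0] == pytest.approx(200.0)

    def test_newton_residual(self, rng):
        """Back-substitution into the assembled push-off equations (with the
        solved-form sign convention for the PA term)."""
        n = 1000
        ff2 = rng.uniform(-500, 500, n)
        fgr2 = rng.uniform(0, 1500, n)
        fpa = rng.uniform(0, 700, n)
        ap = rng.uniform(-120, 120, (n, 2))
        acc = rng.uniform(-5, 5, (n, 2))
        tacc = rng.uniform(-50, 50, n)
        fax, fay, ma = pushoff_dynamics(ff2, fgr2, fpa, ap, acc, tacc, STATIC)
        rx = ff2 + fpa - fax - STATIC.m_fore * acc[:, 0]
        ry = fgr2 - fay - STATIC.m_fore * acc[:, 1]
        rm = -fay * ap[:, 0] - fax * ap[:, 1] + ma - STATIC.j_fore * tacc * 1e3
        scale = np.abs(fay * ap[:, 0]) + np.abs(fax) + np.abs(fay) + 1.0
        assert np.max(np.abs(rx)) <= 1e-9 * np.max(scale)
        assert np.max(np.abs(ry)) <= 1e-9 * np.max(scale)
        assert np.max(np.abs(rm) / scale) <= 1e-9


class TestArchLoad:
    def test_cases(self, rng):
        assert arch_load(3.0, 4.0) == 5.0
        assert arch_load(0.0, 0.0) == 0.0
        q = rng.uniform(-900, 900, (1000, 2))
        np.testing.assert_allclose(arch_load(q[:, 0], q[:, 1]),
                                   np.hypot(q[:, 0], q[:, 1]), atol=1e-12)


class TestQuasiStaticScaling:
    def test_force_scaling_scales_outputs(self):
        """With zero accelerations, scaling all applied forces by c scales
        FAx, FAy, MA, FAL by c."""
        c = 2.7
        args = dict(theta_b=1.2, l_b=25.0, arch_point=np.array([40.0, 30.0]),
                    rear_acc=np.zeros(2), rear_theta_acc=0.0, inertia=STATIC)
        a = heel_contact_dynamics(ff1=-80.0, fgr1=600.0, fpa=120.0, **args)
        b = heel_contact_dynamics(ff1=-80.0 * c, fgr1=600.0 * c, fpa=120.0 * c, **args)
        np.testing.assert_allclose(b, np.asarray(a) * c, rtol=1e-12)
        assert arch_load(b[0], b[1]) == pytest.approx(c * arch_load(a[0], a[1]))


class TestSeriesDispatch:
    def test_noise_free_fal_matches_truth(self, clean_truth, clean_result):
        """End-to-end arch load within 1% of generator truth at every frame."""
        fal = clean_result.arch_state.fal
        ref = clean_truth.fal_true
        np.testing.assert_allclose(fal, ref, rtol=1e-2)

    def test_pc_frames_follow_root_sum_square(self, clean_result):
        st = clean_result.arch_state
        ph = clean_result.phases
        planar = clean_result.planar
        k = np.flatnonzero(st.phase == PC)
        f = planar.plate_f[:, ph.heel_strike + k, :]
        expected = np.sqrt((f ** 2).sum(axis=(0, 2)))
        np.testing.assert_allclose(st.fal[k], expected, atol=1e-9)

    def test_plate_assignment_matches_phase_labels(self, clean_truth, clean_result):
        """The rear plate carries the load before foot flat, the fore plate
        after heel off: CoP-based assignment must agree with the labels."""
        from archstiff.dynamics import assign_plates
        rear, fore = assign_plates(clean_result.planar, clean_result.phases)
        lab = clean_result.phases.labels()
        assert np.all(rear[lab == "HC"] == 0)
        assert np.all(fore[lab == "PO"] == 1)
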