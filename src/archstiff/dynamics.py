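"""Per-phase free-body equations for the internal arch force.

The stance phase is split into heel contact (HC), plantar contact (PC) and
push-off (PO). During HC only the rearfoot touches the ground and Newton's
second law for the rearfoot yields the internal force (FAx, FAy, MA) that
the forefoot exerts on it at the navicular connection; the body load is
taken equal to the rearfoot's vertical ground reaction. During PC the foot
is treated as a quasi-static whole and the arch load equals the root of the
summed squares of both plates' force components. During PO the same
free-body treatment is applied to the forefoot, with the model origin at
the first metatarsophalangeal joint. Gravity on the foot is neglected
throughout (foot weight is small against the loads involved).

The plantar aponeurosis tension FPA (combined passive stretch and intrinsic
muscle effect) is an input curve, supplied as a fraction of body weight
versus percent of stance; it is not estimated here.

Units: forces N, positions/moment arms mm, moments N*mm (converted to N*m
only at reporting), accelerations m/s^2, inertia kg*m^2.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BadPhaseTime, ClockMismatch
from .phases import HC, PC, PO, normalize_time

#: Default anthropometric fractions (configurable): foot mass as a fraction
#: of body mass, rearfoot/forefoot split, and radius-of-gyration fraction.
FOOT_MASS_FRACTION = 0.0137
REARFOOT_SHARE = 0.6
GYRATION_FRACTION = 0.475


@dataclass(frozen=True)
class SegmentInertia:
    """Masses (kg) and moments of inertia (kg*m^2) of the two segments."""

    m_rear: float
    m_fore: float
    j_rear: float
    j_fore: float

    @classmethod
    def from_anthropometry(cls, body_mass: float, rear_len_mm: float,
                           fore_len_mm: float,
                           foot_mass_fraction: float = FOOT_MASS_FRACTION,
                           rear_share: float = REARFOOT_SHARE,
                           gyration: float = GYRATION_FRACTION):
        """Standard scaling: foot mass = fraction of body mass, split between
        segments, J = m * (gyration * segment length)^2."""
        m_foot = foot_mass_fraction * body_mass
        m_r = rear_share * m_foot
        m_f = (1.0 - rear_share) * m_foot
        return cls(
            m_rear=m_r,
            m_fore=m_f,
            j_rear=m_r * (gyration * rear_len_mm * 1e-3) ** 2,
            j_fore=m_f * (gyration * fore_len_mm * 1e-3) ** 2,
        )


@dataclass
class PATensionCurve:
    """Plantar aponeurosis tension as a fraction of body weight.

    Piecewise-linear in percent of stance. The default shape is a
    placeholder rising to a late-stance peak; replace it with digitized
    values for quantitative use (see docs/methods.md).
    """

    knots: np.ndarray = field(default_factory=lambda: np.array(
        [[0.0, 0.0], [15.0, 0.05], [50.0, 0.3], [80.0, 1.0], [100.0, 0.2]]))

    def __post_init__(self):
        k = np.asarray(self.knots, dtype=float)
        if k.ndim != 2 or k.shape[1] != 2:
            raise BadPhaseTime("PA curve knots must be (percent, fraction) pairs")
        if np.any(np.diff(k[:, 0]) <= 0) or k[0, 0] < 0 or k[-1, 0] > 100:
            raise BadPhaseTime("PA curve percents must strictly increase within [0, 100]")
        if np.any(k[:, 1] < 0):
            raise BadPhaseTime("PA curve fractions must be >= 0")
        self.knots = k

    @classmethod
    def zero(cls):
        return cls(knots=np.array([[0.0, 0.0], [100.0, 0.0]]))


def pa_tension(pct, curve: PATensionCurve, body_weight: float):
    """PA tension (N) at percent-of-stance ``pct`` for a given body weight."""
    p = np.asarray(pct, dtype=float)
    if np.any(p < 0) or np.any(p > 100):
        raise BadPhaseTime("percent of stance must lie in [0, 100]")
    return np.interp(p, curve.knots[:, 0], curve.knots[:, 1]) * body_weight


@dataclass
class ArchLoadState:
    """Per-frame internal arch force across stance.

    fax, fay : N; ma : N*mm; fal : N (arch load magnitude);
    fbw : N (body load); phase : HC/PC/PO label per frame.
    """

    fax: np.ndarray
    fay: np.ndarray
    ma: np.ndarray
    fal: np.ndarray
    fbw: np.ndarray
    phase: np.ndarray


def heel_contact_dynamics(ff1, fgr1, theta_b, l_b, fpa, arch_point,
                          rear_acc, rear_theta_acc, inertia: SegmentInertia):
    """Internal arch force during heel contact (rearfoot free body).

    FAx = Ff1 + FPA - FGR1 cos(theta_B) - mR xddR
    FAy = (1 - sin(theta_B)) FGR1 - mR yddR
    MA  = FGR1 lB + FAy xA - FAx yA - JR thetaddR
    with the body load FBW taken equal to FGR1. Moment terms in N*mm.
    """
    ff1 = np.asarray(ff1, dtype=float)
    fgr1 = np.asarray(fgr1, dtype=float)
    ax = np.asarray(rear_acc, dtype=float)[..., 0]
    ay = np.asarray(rear_acc, dtype=float)[..., 1]
    xa = np.asarray(arch_point, dtype=float)[..., 0]
    ya = np.asarray(arch_point, dtype=float)[..., 1]
    fax = ff1 + fpa - fgr1 * np.cos(theta_b) - inertia.m_rear * ax
    fay = (1.0 - np.sin(theta_b)) * fgr1 - inertia.m_rear * ay
    ma = (fgr1 * l_b + fay * xa - fax * ya
          - inertia.j_rear * np.asarray(rear_theta_acc) * 1e3)
    return fax, fay, ma


def plantar_contact_load(ff1, fgr1, ff2, fgr2):
    """Arch load during plantar contact: sqrt(FGR1^2+Ff1^2+FGR2^2+Ff2^2)."""
    return np.sqrt(np.square(fgr1) + np.square(ff1)
                   + np.square(fgr2) + np.square(ff2))


def pushoff_dynamics(ff2, fgr2, fpa, arch_point_fore,
                     fore_acc, fore_theta_acc, inertia: SegmentInertia):
    """Internal arch force during push-off (forefoot free body, MTPJ origin).

    FAx = Ff2 + FPA - mF xddF
    FAy = FGR2 - mF yddF
    MA  = FAy x'A + FAx y'A + JF thetaddF
    """
    ff2 = np.asarray(ff2, dtype=float)
    fgr2 = np.asarray(fgr2, dtype=float)
    ax = np.asarray(fore_acc, dtype=float)[..., 0]
    ay = np.asarray(fore_acc, dtype=float)[..., 1]
    xa = np.asarray(arch_point_fore, dtype=float)[..., 0]
    ya = np.asarray(arch_point_fore, dtype=float)[..., 1]
    fax = ff2 + fpa - inertia.m_fore * ax
    fay = fgr2 - inertia.m_fore * ay
    ma = fay * xa + fax * ya + inertia.j_fore * np.asarray(fore_theta_acc) * 1e3
    return fax, fay, ma


def arch_load(fax, fay):
    """Arch load magnitude FAL = sqrt(FAx^2 + FAy^2)."""
    return np.hypot(fax, fay)


def assign_plates(planar, phases, min_load: float = 50.0):
    """Per stance frame, indices of the rear- and fore-foot plates.

    A plate whose vertical load exceeds ``min_load`` is classified by its
    centre of pressure relative to the navicular ground projection (behind
    -> rearfoot, ahead -> forefoot). Below that load the CoP is unreliable
    and the assignment falls back to the phase label (HC -> the rear slot
    keeps the loaded plate, PO -> the fore slot does).

    Returns (rear_idx, fore_idx) integer arrays of length n_stance.
    """
    hs, to = phases.heel_strike, phases.toe_off
    nav_x = planar.markers["NAV"][hs:to, 0]
    fz = planar.plate_f[:, hs:to, 1]
    cop = planar.plate_cop[:, hs:to]
    labels = phases.labels()
    n = to - hs
    rear = np.zeros(n, dtype=int)
    fore = np.ones(n, dtype=int)
    for i in range(n):
        loaded = np.flatnonzero(fz[:, i] >= min_load)
        if len(loaded) >= 1:
            behind = [p for p in loaded if cop[p, i] < nav_x[i]]
            ahead = [p for p in loaded if cop[p, i] >= nav_x[i]]
            if behind:
                rear[i] = behind[0]
            if ahead:
                fore[i] = ahead[0]
            if not behind and labels[i] == HC:
                rear[i] = loaded[0]
            if not ahead and labels[i] == PO:
                fore[i] = loaded[0]
        else:
            # unloaded/noisy frame: phase-based fallback
            rear[i], fore[i] = 0, 1
    return rear, fore


def compute_arch_load_series(planar, phases, geom, inertia: SegmentInertia,
                             pa_curve: PATensionCurve, body_weight: float) -> ArchLoadState:
    """Evaluate the phase-dispatched free-body equations over stance.

    Per stance frame the phase label selects the governing equations:
    HC -> rearfoot free body, PC -> whole-foot quasi-static load,
    PO -> forefoot free body. Plate-to-segment assignment is CoP-based with
    a phase fallback at low load. FAx/FAy/MA are NaN on PC frames (the
    quasi-static treatment yields only the load magnitude there).
    """
    hs, to = phases.heel_strike, phases.toe_off
    n = to - hs
    if not (len(geom.h) >= to and planar.plate_f.shape[1] >= to):
        raise ClockMismatch("geometry/plate series shorter than stance window")
    labels = phases.labels()
    pct = normalize_time((hs, to))
    fpa = pa_tension(pct, pa_curve, body_weight)
    rear_idx, fore_idx = assign_plates(planar, phases)

    sl = slice(hs, to)
    idx = np.arange(n)
    f_rear = planar.plate_f[rear_idx, hs + idx]     # (n, 2): Ff, FGR
    f_fore = planar.plate_f[fore_idx, hs + idx]

    fax = np.full(n, np.nan)
    fay = np.full(n, np.nan)
    ma = np.full(n, np.nan)
    fal = np.zeros(n)
    fbw = np.zeros(n)

    m_hc = labels == HC
    if m_hc.any():
        k = np.flatnonzero(m_hc)
        fax[k], fay[k], ma[k] = heel_contact_dynamics(
            f_rear[k, 0], f_rear[k, 1], geom.theta_b[sl][k], geom.l_b[sl][k],
            fpa[k], geom.arch_rear[sl][k], geom.rear.com_acc[sl][k],
            geom.rear.theta_acc[sl][k], inertia)
        fal[k] = arch_load(fax[k], fay[k])
        fbw[k] = f_rear[k, 1]

    m_pc = labels == PC
    if m_pc.any():
        k = np.flatnonzero(m_pc)
        fal[k] = plantar_contact_load(f_rear[k, 0], f_rear[k, 1],
                                      f_fore[k, 0], f_fore[k, 1])
        fbw[k] = fal[k]

    m_po = labels == PO
    if m_po.any():
        k = np.flatnonzero(m_po)
        fax[k], fay[k], ma[k] = pushoff_dynamics(
            f_fore[k, 0], f_fore[k, 1], fpa[k], geom.arch_fore[sl][k],
            geom.fore.com_acc[sl][k], geom.fore.theta_acc[sl][k], inertia)
        fal[k] = arch_load(fax[k], fay[k])
        fbw[k] = f_fore[k, 1]

    return ArchLoadState(fax=fax, fay=fay, ma=ma, fal=fal, fbw=fbw, phase=labels)
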