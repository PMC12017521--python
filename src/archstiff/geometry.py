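"""Arch geometry: height, NNHt, MTPJ angle, load direction, segment states.

All positions are in mm in the 2D arch plane (x anteroposterior, y vertical).
Arch height h is the perpendicular distance from the navicular marker to the
calcaneus--first-metatarsal line; NNHt normalizes it by the truncated foot
length. Segment poses use the landmark pairs bounding each segment:
rearfoot CAL--NAV, forefoot NAV--MET1.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import BadMeta, DegenerateFrame, TooShort


@dataclass
class SegmentState:
    """Planar pose and acceleration series of one foot segment.

    com : (N, 2) centre-of-mass position, mm.
    com_acc : (N, 2) centre-of-mass acceleration, m/s^2.
    theta : (N,) orientation, rad, unwrapped.
    theta_acc : (N,) angular acceleration, rad/s^2.
    length_mm : representative segment length (bounding-landmark distance).
    """

    com: np.ndarray
    com_acc: np.ndarray
    theta: np.ndarray
    theta_acc: np.ndarray
    length_mm: float


@dataclass
class ArchGeometrySeries:
    """Per-frame geometric quantities entering the dynamics equations."""

    h: np.ndarray                  # arch height, mm
    height_dir: np.ndarray         # (N, 2) unit vector along which h is measured
    nnht: np.ndarray               # dimensionless
    mtpj_deg: np.ndarray           # MTPJ dorsiflexion, degrees
    theta_b: np.ndarray            # body-load direction, rad, in (0, pi)
    l_b: np.ndarray                # signed moment arm of FBW about O, mm
    arch_rear: np.ndarray          # (N, 2) navicular in rearfoot frame (origin O), mm
    arch_fore: np.ndarray          # (N, 2) navicular in forefoot frame (MTPJ origin), mm
    rear: SegmentState | None = None
    fore: SegmentState | None = None


def arch_height(nav, cal, met1, min_base: float = 1.0):
    """Perpendicular distance (mm) from NAV to the CAL--MET1 line.

    Returns ``(h, direction)``: h >= 0 and the unit vector from the foot of
    the perpendicular toward NAV. Vectorized over leading axes.
    """
    nav = np.asarray(nav, dtype=float)
    cal = np.asarray(cal, dtype=float)
    met1 = np.asarray(met1, dtype=float)
    base = met1 - cal
    blen = np.linalg.norm(base, axis=-1)
    if np.any(blen < min_base):
        raise DegenerateFrame("CAL and MET1 coincide (base < 1 mm)")
    u = base / blen[..., None]
    rel = nav - cal
    along = np.einsum("...i,...i->...", rel, u)
    foot = cal + along[..., None] * u
    perp = nav - foot
    h = np.linalg.norm(perp, axis=-1)
    # where NAV sits exactly on the line, fall back to the +90 deg normal
    normal = np.stack([-u[..., 1], u[..., 0]], axis=-1)
    tiny = h < 1e-12
    direction = np.where(tiny[..., None], normal, perp / np.where(h, h, 1.0)[..., None])
    return h, direction


def nnht(h, truncated_foot_length: float):
    """Normalized navicular height truncation: h / truncated foot length."""
    if truncated_foot_length <= 0:
        raise BadMeta(f"truncated foot length must be > 0, got {truncated_foot_length}")
    return np.asarray(h, dtype=float) / truncated_foot_length


def mtpj_angle(met1, hlx, cal):
    """Signed MTPJ dorsiflexion angle in degrees.

    Angle between the forefoot line CAL->MET1 and the toe vector MET1->HLX;
    positive when the hallux lies dorsal (above) the forefoot line.
    """
    met1 = np.asarray(met1, dtype=float)
    hlx = np.asarray(hlx, dtype=float)
    cal = np.asarray(cal, dtype=float)
    v1 = met1 - cal
    v2 = hlx - met1
    n1 = np.linalg.norm(v1, axis=-1)
    n2 = np.linalg.norm(v2, axis=-1)
    if np.any(n1 < 1e-9) or np.any(n2 < 1e-9):
        raise DegenerateFrame("zero-length vector in MTPJ angle")
    cross = v1[..., 0] * v2[..., 1] - v1[..., 1] * v2[..., 0]
    dot = np.einsum("...i,...i->...", v1, v2)
    return np.degrees(np.arctan2(cross, dot))


def body_load_direction(ank, shk):
    """Direction theta_B (rad) of the body load on the rearfoot, in (0, pi).

    theta_B is the angle between the downward shank axis (SHK->ANK) and the
    in-plane x axis; a vertical shank gives pi/2, a shank tilted forward of
    vertical gives less than pi/2.
    """
    ank = np.asarray(ank, dtype=float)
    shk = np.asarray(shk, dtype=float)
    up = shk - ank
    if np.any(np.linalg.norm(up, axis=-1) < 1.0):
        raise DegenerateFrame("ANK and SHK coincide")
    return np.arctan2(up[..., 1], up[..., 0])


def _second_diff(x: np.ndarray, rate: float) -> np.ndarray:
    """Centered second differences; one-sided (copied) at the ends."""
    n = x.shape[0]
    acc = np.zeros_like(x)
    acc[1:-1] = (x[2:] - 2 * x[1:-1] + x[:-2]) * rate * rate
    acc[0] = acc[1]
    acc[-1] = acc[-2]
    return acc


def segment_states(planar, rear_fraction: float = 0.5, fore_fraction: float = 0.5):
    """Rearfoot and forefoot pose/acceleration series from a PlanarTrial.

    Rearfoot CoM sits ``rear_fraction`` of the way along CAL->NAV, forefoot
    CoM ``fore_fraction`` along NAV->MET1 (midpoints by default). Segment
    orientations are the landmark-pair angles, unwrapped; accelerations are
    centered second differences at the marker rate, in m/s^2 and rad/s^2.
    """
    cal, nav, met1 = (planar.markers[k] for k in ("CAL", "NAV", "MET1"))
    n = len(cal)
    if n < 5:
        raise TooShort(f"need >= 5 frames to differentiate, got {n}")
    rate = planar.rate

    def make(p0, p1, frac):
        com = p0 + frac * (p1 - p0)
        d = p1 - p0
        theta = np.unwrap(np.arctan2(d[:, 1], d[:, 0]))
        return SegmentState(
            com=com,
            com_acc=_second_diff(com, rate) * 1e-3,   # mm/s^2 -> m/s^2
            theta=theta,
            theta_acc=_second_diff(theta, rate),
            length_mm=float(np.mean(np.linalg.norm(d, axis=1))),
        )

    return make(cal, nav, rear_fraction), make(nav, met1, fore_fraction)


def load_geometry(planar, phases):
    """Arch-point coordinates and body-load moment arm per frame.

    The rearfoot frame origin O is the ground projection of the calcaneus
    marker at heel strike; (xA, yA) is NAV relative to O. The forefoot frame
    origin is the per-frame ground projection of MET1; (x'A, y'A) is NAV
    relative to it. l_B is the signed horizontal lever of the body-load line
    of action (through ANK at angle theta_B) about O.
    """
    cal, nav, met1 = (planar.markers[k] for k in ("CAL", "NAV", "MET1"))
    ank, shk = planar.markers["ANK"], planar.markers["SHK"]
    theta_b = body_load_direction(ank, shk)
    origin = np.array([cal[phases.heel_strike, 0], 0.0])
    arch_rear = nav - origin
    fore_origin = np.stack([met1[:, 0], np.zeros(len(met1))], axis=1)
    arch_fore = nav - fore_origin
    # intersection of the load line with the ground, relative to O
    with np.errstate(divide="ignore", invalid="ignore"):
        x_int = ank[:, 0] - ank[:, 1] / np.tan(theta_b)
    l_b = x_int - origin[0]
    return arch_rear, arch_fore, l_b, theta_b


def compute_geometry_series(planar, meta, phases,
                            rear_fraction: float = 0.5,
                            fore_fraction: float = 0.5) -> ArchGeometrySeries:
    """Assemble the full per-frame geometry series for a planar trial."""
    h, hdir = arch_height(planar.markers["NAV"], planar.markers["CAL"],
                          planar.markers["MET1"])
    arch_rear, arch_fore, l_b, theta_b = load_geometry(planar, phases)
    rear, fore = segment_states(planar, rear_fraction, fore_fraction)
    return ArchGeometrySeries(
        h=h,
        height_dir=hdir,
        nnht=nnht(h, meta.truncated_foot_length),
        mtpj_deg=mtpj_angle(planar.markers["MET1"], planar.markers["HLX"],
                            planar.markers["CAL"]),
        theta_b=theta_b,
        l_b=l_b,
        arch_rear=arch_rear,
        arch_fore=arch_fore,
        rear=rear,
        fore=fore,
    )
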