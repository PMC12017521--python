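"""Forward construction of synthetic walking trials with exact ground truth.

The generator builds marker trajectories and dual force-plate records whose
arch mechanics follow prescribed per-phase stiffnesses, providing ground
truth for every pipeline stage. It inverts the estimator's own free-body
equations rather than running an independent physics engine: that choice
gives machine-precision ground truth for unit tests (an independent
forward-dynamics cross-check is out of scope).

Construction outline
--------------------
1. A stance timeline is laid out at the marker rate: a standing lead-in,
   a short transition into the heel-strike pose, the three stance phases
   at the configured fractions, and a trailing unloaded segment.
2. Smooth marker trajectories are designed so that the 20 mm marker-height
   crossings of the *filtered* trajectories land on the configured phase
   boundaries, and the navicular marker is placed to realize a designed
   arch-height curve h(t): linear descent through heel contact and plantar
   contact, a brief further dip at the start of push-off, then a rapid rise.
3. The arch-directed force F_par is prescribed piecewise-linearly in the
   achieved (post-filter) arch height so that each phase interior obeys its
   configured stiffness; the push-off mid-segment slope is solved in closed
   form so the least-squares fit over the end-of-push-off window equals the
   configured k_PO exactly, while the terminal tail is compliant.
4. Plate forces are backed out per frame: plantar-contact frames from the
   root-sum-square load split across the two plates on the unit circle;
   heel-contact and push-off frames by minimum-norm inversion of the
   free-body equations in the (friction, vertical) force pair, using the
   same filtered kinematics, PA-tension curve, and inertia the analyzer
   will use.
5. The 1000 Hz plate records are obtained by an equality-constrained
   smoothing deconvolution, so that the analyzer's filter-and-decimate
   stage reproduces the inverted 100 Hz targets to machine precision.
6. Seeded Gaussian noise is added last (marker noise at the marker rate,
   plate noise at the plate rate).

The resulting plate-force magnitudes during heel contact exceed
physiological values; see docs/methods.md for why this is a deliberate
consequence of making a 7 mm heel-contact arch excursion identifiable.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import numpy as np
from scipy.interpolate import PchipInterpolator
from scipy.linalg import lu_factor, lu_solve

from .dynamics import PATensionCurve, SegmentInertia, pa_tension
from .errors import InfeasibleConfig
from .geometry import arch_height, body_load_direction, segment_states
from .io import ForcePlateSeries, MarkerSet, Trial, TrialMeta, write_trial
from .phases import StancePhases, normalize_time
from .preprocess import PlanarTrial, moving_average
from .stiffness import fit_windows

DEFAULT_MARKER_WINDOW = 7
DEFAULT_GRF_WINDOW = 21

# timeline layout (marker frames)
N_STAND = 8        # flat standing lead-in
N_TRANS = 7        # standing -> heel-strike pose transition
N_TAIL = 10        # unloaded trailing frames

# geometry constants, mm (flat standing pose)
CAL_FLAT = (0.0, 15.0)
MET1_FLAT_Y = 18.0
HLX_OFFSET_X = 55.0
HLX_FLAT_Y = 10.0
ANK_FLAT = (45.0, 67.0)
SHANK_LEN = 330.0
NAV_FRACTION = 0.45
MET1_Y_STRIKE = 95.0          # first-metatarsal marker height at heel strike
CAL_RISE = 120.0              # heel marker height at toe off
CAL_FORWARD = 60.0            # heel forward travel during push-off

# arch-height allocation (fractions of the configured arch drop)
HC_DROP_FRAC = 0.43
DIP_FRAC = 0.10
RECOIL_SHORTFALL = 0.25       # h at toe off = static - this * drop

# force-law anchors
F_HC_END_N = 25.0             # arch-directed force at foot flat (HC side)
PC_LOAD_BW = 1.0              # arch load at foot flat, fraction of body weight
PO_EARLY_SLOPE_FACTOR = 3.0   # early push-off slope = factor * k_po
PO_TAIL_SLOPE_FACTOR = 2.0    # terminal slope = factor * k_pc (compliant)
PO_TAIL_FRAC = 0.15           # terminal tail = last 15% of push-off
PO_DIP_FRAC = 0.25            # dip bottom at 25% of push-off

# reference force profiles for the minimum-norm inversion (N)
FF1_REF_BW = -0.08            # rearfoot friction at heel strike, x body weight
FGR1_REF_LO, FGR1_REF_HI = 150.0, 650.0
FF2_REF_BW = 0.10
FGR2_REF_BW = 0.95

COP_REAR_X = 25.0
COP_FORE_X = 205.0

THETA_B_DEG = {"stand": 90.0, "strike": 68.0, "flat": 72.0, "late": 80.0}


@dataclass(frozen=True)
class SyntheticGaitConfig:
    """Study conditions emulated by the generator.

    Defaults follow the cohort means of the reference table bundled with
    the package (static NNHt 0.162, maximum displacement 0.082 NNHt,
    per-phase stiffness 0.128/0.0069/0.042 kN/mm rounded to the canonical
    recovery targets 0.12/0.007/0.04).
    """

    stance_duration: float = 0.7            # s
    phase_fractions: tuple = (0.15, 0.45, 0.40)
    k_targets: tuple = (0.12, 0.007, 0.04)  # kN/mm: HC, PC, PO
    body_mass: float = 66.6                 # kg
    truncated_foot_length: float = 197.0    # mm
    static_nnht: float = 0.162
    arch_drop: float = 0.082                # NNHt units
    marker_noise_sd: float = 0.0            # mm
    grf_noise_sd: float = 0.0               # N
    seed: int = 0
    marker_rate: float = 100.0              # Hz
    grf_rate: float = 1000.0                # Hz

    def validate(self):
        f = np.asarray(self.phase_fractions, dtype=float)
        if len(f) != 3 or np.any(f <= 0) or abs(f.sum() - 1.0) > 1e-9:
            raise InfeasibleConfig("phase fractions must be positive and sum to 1")
        if np.any(np.asarray(self.k_targets) <= 0):
            raise InfeasibleConfig("stiffness targets must be > 0")
        if self.marker_noise_sd < 0 or self.grf_noise_sd < 0:
            raise InfeasibleConfig("noise levels must be >= 0")
        if self.arch_drop >= self.static_nnht:
            raise InfeasibleConfig(
                f"arch_drop {self.arch_drop} >= static NNHt {self.static_nnht}: "
                "arch height would go negative")
        if self.body_mass <= 0 or self.truncated_foot_length <= 0:
            raise InfeasibleConfig("mass and foot length must be > 0")
        ratio = self.grf_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise InfeasibleConfig("grf_rate must be an integer multiple of marker_rate")


@dataclass
class GroundTruth:
    """Per-stance-frame ground truth emitted beside the trial.

    Heights refer to the *filtered* marker trajectories, i.e. what the
    analysis pipeline measures; phases are the configured boundaries.
    """

    phases: StancePhases
    h_true: np.ndarray              # mm
    f_along_h_true: np.ndarray      # N
    fal_true: np.ndarray            # N
    phase_true: np.ndarray          # labels
    k_true: np.ndarray              # kN/mm, per-frame prescribed slope
    k_targets: tuple                # (HC, PC, PO) fitted-window truths
    static_nnht: float
    arch_drop: float
    slope_change_frames: np.ndarray  # stance-relative frames where k_true changes


# --- deconvolution ---------------------------------------------------------

_KKT_CACHE: dict = {}


def _pipeline_matrix(n_frames: int, factor: int, grf_window: int) -> np.ndarray:
    """Dense matrix of the analyzer's GRF filter-and-decimate stage."""
    m = n_frames * factor
    eye = np.eye(m)
    a = moving_average(eye, grf_window)
    w = factor if factor % 2 == 1 else factor + 1
    a = moving_average(a, w)
    return a[::factor]


def _grf_deconvolver(n_frames: int, factor: int, grf_window: int):
    """Solver mapping 100 Hz targets to 1000 Hz series.

    Returns a function t -> v minimizing the curvature ||D2 v||^2 subject
    to the analyzer's filtered, decimated output equalling t exactly.
    """
    key = (n_frames, factor, grf_window)
    if key not in _KKT_CACHE:
        p = _pipeline_matrix(n_frames, factor, grf_window)
        m = p.shape[1]
        d2 = (np.diag(np.full(m, -2.0)) + np.diag(np.ones(m - 1), 1)
              + np.diag(np.ones(m - 1), -1))[1:-1]
        top = 2.0 * d2.T @ d2 + 1e-9 * np.eye(m)
        kkt = np.block([[top, p.T], [p, np.zeros((p.shape[0], p.shape[0]))]])
        _KKT_CACHE[key] = (lu_factor(kkt), m, p.shape[0])
    lu, m, nt = _KKT_CACHE[key]

    def solve(target: np.ndarray) -> np.ndarray:
        rhs = np.concatenate([np.zeros(m), target])
        return lu_solve(lu, rhs)[:m]

    return solve


# --- trajectory design -----------------------------------------------------

def _pchip(frames, values, n):
    """Piecewise-cubic monotone interpolant sampled on 0..n-1, held constant
    outside the knot span."""
    f = PchipInterpolator(frames, values)
    t = np.arange(n, dtype=float)
    out = f(np.clip(t, frames[0], frames[-1]))
    return out


def _design_markers(cfg: SyntheticGaitConfig, lay: dict) -> dict:
    """Raw (pre-noise) 2D marker trajectories in the sagittal plane."""
    n, hs, ff, ho, to = (lay[k] for k in ("n", "hs", "ff", "ho", "to"))
    L = cfg.truncated_foot_length

    met1_y = np.full(n, MET1_FLAT_Y)
    # transition: flat -> heel-strike pose; descent knots put the filtered
    # 20 mm crossing exactly at the configured foot-flat frame
    rise = _pchip([N_STAND - 1, hs], [MET1_FLAT_Y, MET1_Y_STRIKE], n)
    met1_y[N_STAND - 1:hs + 1] = rise[N_STAND - 1:hs + 1]
    desc_f = [hs, ff - 5, ff - 4, ff - 3, ff - 2, ff - 1, ff]
    desc_v = [MET1_Y_STRIKE, 40.0, 30.0, 25.0, 21.0, 19.0, MET1_FLAT_Y]
    desc = _pchip(desc_f, desc_v, n)
    met1_y[hs:ff + 1] = desc[hs:ff + 1]
    met1_x = np.full(n, L)

    cal_y = np.full(n, CAL_FLAT[1])
    rise_f = [ho - 1, ho, ho + 1, ho + 2, ho + 3, to]
    rise_v = [CAL_FLAT[1], 20.0, 24.0, 29.0, 34.0, CAL_RISE]
    calr = _pchip(rise_f, rise_v, n)
    cal_y[ho - 1:] = calr[ho - 1:]
    cal_x = np.zeros(n)
    cal_x[ho:] = _pchip([ho, to], [0.0, CAL_FORWARD], n)[ho:]

    hlx_x = np.full(n, L + HLX_OFFSET_X)
    hlx_y = HLX_FLAT_Y + 1.28 * np.maximum(met1_y - MET1_FLAT_Y, 0.0)

    ank_x = ANK_FLAT[0] + cal_x
    ank_y = ANK_FLAT[1] + 0.85 * (cal_y - CAL_FLAT[1])
    tb = np.radians(_pchip(
        [N_STAND - 1, hs, ff, ho, to],
        [THETA_B_DEG["stand"], THETA_B_DEG["strike"], THETA_B_DEG["flat"],
         THETA_B_DEG["late"], THETA_B_DEG["late"]], n))
    shk_x = ank_x + SHANK_LEN * np.cos(tb)
    shk_y = ank_y + SHANK_LEN * np.sin(tb)

    # designed arch-height law (mm)
    h_static = cfg.static_nnht * L
    drop = cfg.arch_drop * L
    d_hc, dip = HC_DROP_FRAC * drop, DIP_FRAC * drop
    d_pc = drop - d_hc - dip
    h_ff = h_static - d_hc
    h_ho = h_static - d_hc - d_pc
    h_min = h_static - drop
    h_to = h_static - RECOIL_SHORTFALL * drop
    dip_i = ho + lay["dip"]
    h = np.full(n, h_static)
    h[hs:ff + 1] = np.interp(np.arange(hs, ff + 1), [hs, ff], [h_static, h_ff])
    h[ff:ho + 1] = np.interp(np.arange(ff, ho + 1), [ff, ho], [h_ff, h_ho])
    po = PchipInterpolator([ho, dip_i, to], [h_ho, h_min, h_to])
    h[ho:to + 1] = po(np.arange(ho, to + 1))
    h[to:] = h_to

    cal = np.stack([cal_x, cal_y], axis=1)
    met1 = np.stack([met1_x, met1_y], axis=1)
    base = met1 - cal
    blen = np.linalg.norm(base, axis=1)
    u = base / blen[:, None]
    normal = np.stack([-u[:, 1], u[:, 0]], axis=1)
    nav = cal + NAV_FRACTION * blen[:, None] * u + h[:, None] * normal

    return {
        "CAL": cal, "MET1": met1, "NAV": nav,
        "HLX": np.stack([hlx_x, hlx_y], axis=1),
        "ANK": np.stack([ank_x, ank_y], axis=1),
        "SHK": np.stack([shk_x, shk_y], axis=1),
    }


def _layout(cfg: SyntheticGaitConfig) -> dict:
    s = int(round(cfg.stance_duration * cfg.marker_rate))
    f0, f1, _ = cfg.phase_fractions
    n_hc = int(np.floor(f0 * s + 0.5))
    n_hcpc = int(np.floor((f0 + f1) * s + 0.5))
    hs = N_STAND + N_TRANS
    lay = {
        "n": hs + s + N_TAIL, "hs": hs, "ff": hs + n_hc,
        "ho": hs + n_hcpc, "to": hs + s, "s": s,
        "dip": int(np.floor(PO_DIP_FRAC * (s - n_hcpc) + 0.5)),
    }
    if n_hc < 8 or (n_hcpc - n_hc) < 6 or (s - n_hcpc) < 14:
        raise InfeasibleConfig(
            f"phase lengths {n_hc}/{n_hcpc - n_hc}/{s - n_hcpc} frames too short "
            "for the generator's trajectory templates")
    return lay


def _force_law(cfg, lay, h, po_fit_frames):
    """Per-stance-frame arch-directed force law and per-frame slope (N, N/mm)."""
    hs, ff, ho, to = (lay[k] for k in ("hs", "ff", "ho", "to"))
    bw = cfg.body_mass * 9.81
    k_hc, k_pc, k_po = (1e3 * k for k in cfg.k_targets)  # N/mm
    n_po = to - ho
    mid_i = ho + int(np.floor(n_po / 3.0 + 0.5))          # end of early slope
    tail_i = to - max(3, int(np.floor(PO_TAIL_FRAC * n_po + 0.5)))
    s_early = PO_EARLY_SLOPE_FACTOR * k_po
    s_tail = PO_TAIL_SLOPE_FACTOR * k_pc

    slope = np.zeros(lay["n"])
    slope[hs:ff] = k_hc
    slope[ff:ho] = k_pc
    slope[ho:mid_i] = s_early
    slope[mid_i:tail_i] = np.nan                          # solved below
    slope[tail_i:to] = s_tail

    f = np.zeros(lay["n"])
    f[hs:ff] = F_HC_END_N + k_hc * (h[hs:ff] - h[ff])
    f[ff:ho] = -PC_LOAD_BW * bw + k_pc * (h[ff:ho] - h[ff])

    def integrate(s_mid):
        sl = np.where(np.isnan(slope[ho:to]), s_mid, slope[ho:to])
        out = np.empty(to - ho)
        out[0] = 0.0
        out[1:] = np.cumsum(sl[:-1] * np.diff(h[ho:to]))
        return out

    # solve s_mid so the OLS slope over the end-of-push-off window equals
    # k_po exactly (the fitted value is affine in s_mid)
    w = po_fit_frames
    x = h[hs + w]

    def ols(s_mid):
        y = integrate(s_mid)[w - (ho - hs)]
        xm, ym = x.mean(), y.mean()
        return np.dot(x - xm, y - ym) / np.dot(x - xm, x - xm)

    b0, b1 = ols(0.0), ols(1.0)
    if abs(b1 - b0) < 1e-12:
        raise InfeasibleConfig("push-off fit window does not span the mid segment")
    s_mid = (k_po - b0) / (b1 - b0)
    if s_mid <= 0:
        raise InfeasibleConfig(f"solved push-off mid slope {s_mid:.3g} <= 0")
    slope[mid_i:tail_i] = s_mid

    anchor = np.nan  # filled by caller (forward value at heel off)
    f[ho:to] = integrate(s_mid)  # relative; caller adds the anchor
    changes = np.array([hs, ff, ho, ho + lay["dip"], mid_i, tail_i, to]) - hs
    return f, slope, changes


# --- main construction -----------------------------------------------------

def _construct(cfg: SyntheticGaitConfig):
    """Noise-free trial construction; returns (trial, truth, targets100)."""
    cfg.validate()
    lay = _layout(cfg)
    n, hs, ff, ho, to = (lay[k] for k in ("n", "hs", "ff", "ho", "to"))
    raw = _design_markers(cfg, lay)
    bw = cfg.body_mass * 9.81

    # what the analyzer will measure: filtered markers and derived geometry
    filt = {k: moving_average(v, DEFAULT_MARKER_WINDOW) for k, v in raw.items()}
    planar = PlanarTrial(markers=filt, rate=cfg.marker_rate)
    h, hdir = arch_height(filt["NAV"], filt["CAL"], filt["MET1"])
    theta_b = body_load_direction(filt["ANK"], filt["SHK"])
    rear, fore = segment_states(planar)
    inertia = SegmentInertia.from_anthropometry(
        cfg.body_mass, rear.length_mm, fore.length_mm)

    # verify the filtered 20 mm crossings land on the configured boundaries
    ff_d = hs + int(np.argmax(filt["MET1"][hs:to, 1] < 20.0))
    ho_d = ff + 1 + int(np.argmax(filt["CAL"][ff + 1:to, 1] >= 20.0))
    if ff_d != ff or ho_d != ho:
        raise InfeasibleConfig(
            f"filtered marker-height crossings ({ff_d}, {ho_d}) missed the "
            f"configured boundaries ({ff}, {ho})")

    phases = StancePhases(hs, ff, ho, to)
    po_w = hs + fit_windows(phases)["PO"]
    f_par, slope, changes = _force_law(cfg, lay, h, po_w - hs)

    pct = normalize_time((hs, to))
    pa_curve = PATensionCurve()
    fpa = np.zeros(n)
    fpa[hs:to] = pa_tension(pct, pa_curve, bw)

    # reference force profiles (the minimum-norm inversion stays near these)
    ff1_ref = np.interp(np.arange(n), [hs, ff], [FF1_REF_BW * bw, -30.0])
    fgr1_ref = np.interp(np.arange(n), [hs, ff], [FGR1_REF_LO, FGR1_REF_HI])
    ff2_ref = np.full(n, FF2_REF_BW * bw)
    fgr2_ref = np.full(n, FGR2_REF_BW * bw)

    grf = np.zeros((2, n, 2))  # plate, frame, (Ff, FGR) targets at marker rate

    hx, hy = hdir[:, 0], hdir[:, 1]
    # heel contact: solve (Ff1, FGR1) nearest the reference profile
    i = np.arange(hs, ff)
    a_f = hx[i]
    a_g = -np.cos(theta_b[i]) * hx[i] + (1.0 - np.sin(theta_b[i])) * hy[i]
    c0 = ((fpa[i] - inertia.m_rear * rear.com_acc[i, 0]) * hx[i]
          - inertia.m_rear * rear.com_acc[i, 1] * hy[i])
    base = a_f * ff1_ref[i] + a_g * fgr1_ref[i] + c0
    r = (f_par[i] - base) / (a_f ** 2 + a_g ** 2)
    grf[0, i, 0] = ff1_ref[i] + a_f * r
    grf[0, i, 1] = fgr1_ref[i] + a_g * r
    if np.any(grf[0, i, 1] < 35.0):
        raise InfeasibleConfig("heel-contact inversion drove FGR1 below threshold")

    # plantar contact: root-sum-square load split on the unit circle
    i = np.arange(ff, ho)
    fal_pc = -f_par[i]
    wgt = (i - ff) / max(ho - 1 - ff, 1)
    grf[0, i, 1] = np.cos(wgt * np.pi / 2) * fal_pc
    grf[1, i, 1] = np.sin(wgt * np.pi / 2) * fal_pc

    # push-off: anchor the law at the forward value with reference forces,
    # then solve (Ff2, FGR2) nearest the reference profile
    i = np.arange(ho, to)
    c0 = ((fpa[i] - inertia.m_fore * fore.com_acc[i, 0]) * hx[i]
          - inertia.m_fore * fore.com_acc[i, 1] * hy[i])
    anchor = (hx[ho] * ff2_ref[ho] + hy[ho] * fgr2_ref[ho] + c0[0])
    f_par[i] += anchor
    base = hx[i] * ff2_ref[i] + hy[i] * fgr2_ref[i] + c0
    r = (f_par[i] - base) / (hx[i] ** 2 + hy[i] ** 2)
    grf[1, i, 0] = ff2_ref[i] + hx[i] * r
    grf[1, i, 1] = fgr2_ref[i] + hy[i] * r
    if np.any(grf[1, i, 1] < 35.0):
        raise InfeasibleConfig("push-off inversion drove FGR2 below threshold")

    # sub-threshold ramps at the stance edges keep detection exact while
    # limiting deconvolution ringing
    grf[0, hs - 2, 1], grf[0, hs - 1, 1] = 6.0, 18.0
    grf[1, to, 1], grf[1, to + 1, 1] = 15.0, 5.0

    # ground-truth internal force (from the inverted plate forces)
    fal = np.zeros(to - hs)
    lab = phases.labels()
    j = np.arange(hs, ff) - hs
    fax = (grf[0, hs:ff, 0] + fpa[hs:ff]
           - grf[0, hs:ff, 1] * np.cos(theta_b[hs:ff])
           - inertia.m_rear * rear.com_acc[hs:ff, 0])
    fay = ((1 - np.sin(theta_b[hs:ff])) * grf[0, hs:ff, 1]
           - inertia.m_rear * rear.com_acc[hs:ff, 1])
    fal[j] = np.hypot(fax, fay)
    fal[ff - hs:ho - hs] = -f_par[ff:ho]
    fax = (grf[1, ho:to, 0] + fpa[ho:to] - inertia.m_fore * fore.com_acc[ho:to, 0])
    fay = grf[1, ho:to, 1] - inertia.m_fore * fore.com_acc[ho:to, 1]
    fal[ho - hs:] = np.hypot(fax, fay)

    truth = GroundTruth(
        phases=phases,
        h_true=h[hs:to].copy(),
        f_along_h_true=f_par[hs:to].copy(),
        fal_true=fal,
        phase_true=lab,
        k_true=slope[hs:to] * 1e-3,
        k_targets=cfg.k_targets,
        static_nnht=cfg.static_nnht,
        arch_drop=cfg.arch_drop,
        slope_change_frames=changes,
    )
    return lay, raw, grf, truth


def generate_trial(config: SyntheticGaitConfig) -> tuple[Trial, GroundTruth]:
    """Build a synthetic trial and its ground truth.

    Same config (including seed) yields bit-identical output. Noise levels
    of zero give a trial the analysis pipeline reproduces to near machine
    precision.
    """
    lay, raw, grf100, truth = _cached_construct(config)
    n = lay["n"]
    factor = int(round(config.grf_rate / config.marker_rate))
    solve = _grf_deconvolver(n, factor, DEFAULT_GRF_WINDOW)

    m = n * factor
    forces = np.zeros((2, m, 3))
    cop = np.zeros((2, m, 3))
    for p in range(2):
        forces[p, :, 0] = solve(grf100[p, :, 0])   # world x = in-plane Ff
        forces[p, :, 2] = solve(grf100[p, :, 1])   # world z = vertical
    cop[0, :, 0] = COP_REAR_X
    cop[1, :, 0] = COP_FORE_X

    markers = {}
    for name, xy in raw.items():
        pos = np.zeros((n, 3))
        pos[:, 0] = xy[:, 0]
        pos[:, 2] = xy[:, 1]
        markers[name] = pos

    rng = np.random.default_rng(config.seed)
    if config.marker_noise_sd > 0:
        for name in markers:
            markers[name] = markers[name] + rng.normal(
                0.0, config.marker_noise_sd, size=(n, 3))
    if config.grf_noise_sd > 0:
        forces = forces + rng.normal(0.0, config.grf_noise_sd, size=forces.shape)

    meta = TrialMeta(
        subject_id=f"synthetic-{config.seed}", sex="other",
        body_mass=config.body_mass,
        truncated_foot_length=config.truncated_foot_length,
        marker_rate=config.marker_rate, grf_rate=config.grf_rate)
    trial = Trial(meta=meta, markers=MarkerSet(positions=markers),
                  plates=ForcePlateSeries(forces=forces, cop=cop))
    return trial, copy.deepcopy(truth)


_CONSTRUCT_CACHE: dict = {}


def _cached_construct(config: SyntheticGaitConfig):
    """Noise and seed do not enter the deterministic construction, so it is
    cached across seeds (the dominant cost when sweeping noise realisations)."""
    key = (config.stance_duration, config.phase_fractions, config.k_targets,
           config.body_mass, config.truncated_foot_length, config.static_nnht,
           config.arch_drop, config.marker_rate, config.grf_rate)
    if key not in _CONSTRUCT_CACHE:
        noiseless = SyntheticGaitConfig(
            **{**config.__dict__, "marker_noise_sd": 0.0,
               "grf_noise_sd": 0.0, "seed": 0})
        _CONSTRUCT_CACHE[key] = _construct(noiseless)
    return _CONSTRUCT_CACHE[key]


def write_fixture(trial: Trial, truth: GroundTruth, out_dir) -> dict:
    """Write the trial in the CSV dialects plus a ground-truth TSV."""
    import pandas as pd
    from pathlib import Path
    paths = write_trial(trial, out_dir)
    hs = truth.phases.heel_strike
    df = pd.DataFrame({
        "frame": np.arange(hs, truth.phases.toe_off),
        "phase_true": truth.phase_true,
        "h_true_mm": truth.h_true,
        "f_along_h_true_n": truth.f_along_h_true,
        "fal_true_n": truth.fal_true,
        "k_true_kn_per_mm": truth.k_true,
    })
    truth_path = Path(out_dir) / "truth.tsv"
    df.to_csv(truth_path, sep="\t", index=False, float_format="%.10g")
    paths["truth"] = truth_path
    return paths
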