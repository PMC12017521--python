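"""Continuous arch stiffness, per-phase linear fits, cohort statistics.

The linear arch stiffness is k = dF/dh, the change of the arch-directed
force per change of arch height, reported in kN/mm. The force entering k
is the component of the internal arch force along the direction in which
the height is measured: on heel-contact and push-off frames
F_par = (FAx, FAy) . height_dir; on plantar-contact frames the arch load
magnitude acts compressively along -height_dir, so F_par = -FAL. Negative
k is permitted (the arch force can drop while the height still falls);
frames where the height differential vanishes are flagged invalid rather
than producing infinities.

Per-phase average stiffness is an ordinary least-squares line fitted over
the beginning of heel contact, the whole plantar contact phase, and the
end of push-off; the fit quality is an RMSE normalized by the force range
over the fitted window, in percent.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import BadWindow, DegenerateFit, TooFewSubjects
from .phases import HC, PC, PO, StancePhases


@dataclass
class StiffnessSeries:
    """Per-stance-frame stiffness estimate.

    k : kN/mm (NaN where invalid); f_along_h : N; h : mm;
    valid : bool flag per frame.
    """

    k: np.ndarray
    f_along_h: np.ndarray
    h: np.ndarray
    valid: np.ndarray


@dataclass
class StiffnessSummary:
    """Per-trial summary mirroring the cohort table columns."""

    k_hc: float
    k_pc: float
    k_po: float
    rmse_hc_pct: float
    rmse_pc_pct: float
    rmse_po_pct: float
    static_nnht: float
    max_arch_displacement: float  # NNHt units: static minus stance minimum

    def as_dict(self) -> dict:
        return {
            "k_hc_kn_per_mm": self.k_hc,
            "k_pc_kn_per_mm": self.k_pc,
            "k_po_kn_per_mm": self.k_po,
            "rmse_hc_pct": self.rmse_hc_pct,
            "rmse_pc_pct": self.rmse_pc_pct,
            "rmse_po_pct": self.rmse_po_pct,
            "static_nnht": self.static_nnht,
            "max_arch_displacement_nnht": self.max_arch_displacement,
        }


def force_along_height(arch_state, geom, phases: StancePhases) -> np.ndarray:
    """Arch-directed force per stance frame (N), phase-dispatched."""
    hs, to = phases.heel_strike, phases.toe_off
    hdir = geom.height_dir[hs:to]
    f = np.einsum("ij,ij->i",
                  np.stack([arch_state.fax, arch_state.fay], axis=1), hdir)
    pc = arch_state.phase == PC
    f[pc] = -arch_state.fal[pc]
    return f


def continuous_stiffness(arch_state, geom, phases: StancePhases,
                         window: int = 5, min_dh: float = 0.01) -> StiffnessSeries:
    """Central-difference stiffness k(t) over stance, kN/mm.

    k(i) = [F_par(i+w) - F_par(i-w)] / [h(i+w) - h(i-w)], w = (window-1)/2.
    Frames with |dh| < ``min_dh`` mm or insufficient margin are invalid.
    """
    if window < 3 or window % 2 == 0:
        raise BadWindow(f"window must be odd and >= 3, got {window}")
    hs, to = phases.heel_strike, phases.toe_off
    f = force_along_height(arch_state, geom, phases)
    h = geom.h[hs:to]
    n = to - hs
    w = (window - 1) // 2
    k = np.full(n, np.nan)
    valid = np.zeros(n, dtype=bool)
    i = np.arange(w, n - w)
    dh = h[i + w] - h[i - w]
    df = f[i + w] - f[i - w]
    ok = np.abs(dh) >= min_dh
    k[i[ok]] = df[ok] / dh[ok] * 1e-3
    valid[i[ok]] = True
    return StiffnessSeries(k=k, f_along_h=f, h=h, valid=valid)


def fit_phase_stiffness(f_along_h, h, frames) -> tuple[float, float]:
    """OLS line F_par = a + k*h over ``frames``; (slope kN/mm, RMSE %).

    The RMSE is normalized by the force range over the fitted window so
    that it is scale-free and offset-insensitive.
    """
    idx = np.asarray(frames, dtype=int)
    if len(idx) < 2:
        raise DegenerateFit(f"need >= 2 frames for a line fit, got {len(idx)}")
    x = np.asarray(h, dtype=float)[idx]
    y = np.asarray(f_along_h, dtype=float)[idx]
    if np.ptp(x) < 1e-12:
        raise DegenerateFit("arch height constant over the fit window")
    xm, ym = x.mean(), y.mean()
    slope = float(np.dot(x - xm, y - ym) / np.dot(x - xm, x - xm))
    resid = y - (ym + slope * (x - xm))
    rmse = float(np.sqrt(np.mean(resid ** 2)))
    frange = float(np.ptp(y))
    rmse_pct = 0.0 if frange == 0 else 100.0 * rmse / frange
    return slope * 1e-3, rmse_pct


def _window_len(n: int, fraction: float) -> int:
    return max(3, int(np.floor(n * fraction + 0.5)))


def fit_windows(phases: StancePhases, hc_fraction: float = 0.5,
                po_fraction: float = 1.0 / 3.0) -> dict:
    """Stance-relative frame indices of the three fit windows.

    Heel contact uses its first ``hc_fraction``, plantar contact the whole
    phase, push-off its last ``po_fraction``.
    """
    hs = phases.heel_strike
    ff, ho, to = (phases.foot_flat - hs, phases.heel_off - hs,
                  phases.toe_off - hs)
    n_hc = ff
    n_po = to - ho
    hc_w = np.arange(0, min(ff, _window_len(n_hc, hc_fraction)))
    pc_w = np.arange(ff, ho)
    po_w = np.arange(max(ho, to - _window_len(n_po, po_fraction)), to)
    return {HC: hc_w, PC: pc_w, PO: po_w}


def classification_windows(phases: StancePhases, hc_fraction: float = 0.5,
                           early_po_fraction: float = 1.0 / 3.0,
                           late_po_fraction: float = 0.15) -> list:
    """Four stance-ordered windows for the stiff/compliant pattern:
    early heel contact, plantar contact, early push-off, late push-off."""
    hs = phases.heel_strike
    ff, ho, to = (phases.foot_flat - hs, phases.heel_off - hs,
                  phases.toe_off - hs)
    n_po = to - ho
    return [
        np.arange(0, min(ff, _window_len(ff, hc_fraction))),
        np.arange(ff, ho),
        np.arange(ho, min(to, ho + _window_len(n_po, early_po_fraction))),
        np.arange(max(ho, to - _window_len(n_po, late_po_fraction)), to),
    ]


def summarize_trial(stiff: StiffnessSeries, phases: StancePhases, geom,
                    static_nnht: float, hc_fraction: float = 0.5,
                    po_fraction: float = 1.0 / 3.0) -> StiffnessSummary:
    """Fit the three per-phase stiffnesses and the arch-displacement range."""
    wins = fit_windows(phases, hc_fraction, po_fraction)
    k_hc, rmse_hc = fit_phase_stiffness(stiff.f_along_h, stiff.h, wins[HC])
    k_pc, rmse_pc = fit_phase_stiffness(stiff.f_along_h, stiff.h, wins[PC])
    k_po, rmse_po = fit_phase_stiffness(stiff.f_along_h, stiff.h, wins[PO])
    hs, to = phases.heel_strike, phases.toe_off
    max_disp = float(static_nnht - np.min(geom.nnht[hs:to]))
    return StiffnessSummary(
        k_hc=k_hc, k_pc=k_pc, k_po=k_po,
        rmse_hc_pct=rmse_hc, rmse_pc_pct=rmse_pc, rmse_po_pct=rmse_po,
        static_nnht=static_nnht, max_arch_displacement=max_disp,
    )


#: Columns aggregated by cohort_summary, in report order.
COHORT_COLUMNS = [
    "mass_kg", "truncated_foot_length_mm", "static_nnht",
    "max_arch_displacement_nnht", "k_hc_kn_per_mm", "k_pc_kn_per_mm",
    "k_po_kn_per_mm",
]


def cohort_summary(table: pd.DataFrame) -> pd.DataFrame:
    """Arithmetic mean and sample (n-1) standard deviation per column.

    ``table`` holds one row per subject; all numeric columns are
    aggregated. Returns a two-row DataFrame indexed Mean/STD.
    """
    num = table.select_dtypes(include=[np.number])
    if len(num) < 2:
        raise TooFewSubjects(f"cohort statistics need >= 2 subjects, got {len(num)}")
    return pd.DataFrame({"Mean": num.mean(), "STD": num.std(ddof=1)}).T
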