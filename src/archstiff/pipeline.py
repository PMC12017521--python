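"""End-to-end orchestration: trial -> phases -> geometry -> load -> stiffness."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .config import RunConfig
from .dynamics import (ArchLoadState, SegmentInertia, compute_arch_load_series)
from .geometry import ArchGeometrySeries, compute_geometry_series
from .phases import StancePhases, detect_stance, subdivide_stance
from .preprocess import PlanarTrial, project_to_mla_plane
from .stiffness import (StiffnessSeries, StiffnessSummary, continuous_stiffness,
                        summarize_trial)
from .validation import classify_pattern, pattern_slopes


@dataclass
class AnalysisResult:
    """Everything computed for one trial."""

    planar: PlanarTrial
    phases: StancePhases
    geom: ArchGeometrySeries
    arch_state: ArchLoadState
    stiffness: StiffnessSeries
    summary: StiffnessSummary
    pattern_slopes: np.ndarray
    pattern: list


def analyze_trial(trial, config: RunConfig | None = None) -> AnalysisResult:
    """Run the full arch-stiffness pipeline on one trial."""
    cfg = config or RunConfig()
    planar = project_to_mla_plane(
        trial, marker_window=cfg.marker_window, grf_window=cfg.grf_window,
        plane=cfg.plane)
    fz_total = planar.plate_f[:, :, 1].sum(axis=0)
    stance = detect_stance(fz_total, threshold=cfg.grf_threshold_n,
                           debounce=cfg.debounce_frames)
    phases = subdivide_stance(planar.markers["CAL"][:, 1],
                              planar.markers["MET1"][:, 1], stance,
                              height_threshold=cfg.height_threshold_mm)
    geom = compute_geometry_series(planar, trial.meta, phases,
                                   rear_fraction=cfg.com_rearfoot_fraction,
                                   fore_fraction=cfg.com_forefoot_fraction)
    inertia = SegmentInertia.from_anthropometry(
        trial.meta.body_mass, geom.rear.length_mm, geom.fore.length_mm,
        foot_mass_fraction=cfg.foot_mass_fraction,
        rear_share=cfg.rearfoot_share, gyration=cfg.gyration_fraction)
    arch_state = compute_arch_load_series(planar, phases, geom, inertia,
                                          cfg.pa_curve(),
                                          trial.meta.body_weight)
    stiff = continuous_stiffness(arch_state, geom, phases,
                                 window=cfg.k_window_frames)
    if cfg.static_nnht is not None:
        static_nnht = float(cfg.static_nnht)
    else:
        lo, hi = cfg.static_window
        static_nnht = float(np.mean(geom.nnht[lo:hi]))
    summary = summarize_trial(stiff, phases, geom, static_nnht,
                              hc_fraction=cfg.hc_fraction,
                              po_fraction=cfg.po_fraction)
    slopes = pattern_slopes(stiff, phases, hc_fraction=cfg.hc_fraction)
    return AnalysisResult(
        planar=planar, phases=phases, geom=geom, arch_state=arch_state,
        stiffness=stiff, summary=summary, pattern_slopes=slopes,
        pattern=classify_pattern(slopes))
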