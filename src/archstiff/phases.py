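"""Stance detection and three-phase subdivision.

Stance is detected from the summed vertical ground reaction force with a
30 N threshold (3-frame debounce), and subdivided into heel contact,
plantar contact, and push-off using the heights of the posterior-calcaneus
and first-metatarsal markers against a 20 mm threshold. The 20 mm value
already accounts for marker size, so no radius correction is applied.

Phase convention is half-open: phase p spans [start, next_start).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import NoFootFlat, NoHeelOff, NoStanceDetected

HC, PC, PO = "HC", "PC", "PO"


@dataclass(frozen=True)
class StancePhases:
    """Frame indices delimiting the three stance sub-phases.

    heel contact = [heel_strike, foot_flat), plantar contact =
    [foot_flat, heel_off), push-off = [heel_off, toe_off).
    """

    heel_strike: int
    foot_flat: int
    heel_off: int
    toe_off: int

    def __post_init__(self):
        if not (self.heel_strike < self.foot_flat < self.heel_off < self.toe_off):
            raise NoStanceDetected(
                f"phase ordering violated: {self.heel_strike} < {self.foot_flat} "
                f"< {self.heel_off} < {self.toe_off} required")

    @property
    def n_stance(self) -> int:
        return self.toe_off - self.heel_strike

    def labels(self) -> np.ndarray:
        """Per-stance-frame phase label array of length ``n_stance``."""
        lab = np.empty(self.n_stance, dtype=object)
        lab[: self.foot_flat - self.heel_strike] = HC
        lab[self.foot_flat - self.heel_strike: self.heel_off - self.heel_strike] = PC
        lab[self.heel_off - self.heel_strike:] = PO
        return lab


def _runs_at_least(mask: np.ndarray, k: int) -> np.ndarray:
    """Boolean array: mask[i] starts a run of >= k consecutive True."""
    n = len(mask)
    ok = np.zeros(n, dtype=bool)
    run = 0
    for i in range(n - 1, -1, -1):
        run = run + 1 if mask[i] else 0
        ok[i] = run >= k
    return ok


def detect_stance(fz_total, threshold: float = 30.0, debounce: int = 3):
    """Locate (heel_strike, toe_off) from the summed vertical GRF.

    heel_strike is the first index where ``fz >= threshold`` holds for at
    least ``debounce`` consecutive frames; toe_off the first later index
    where ``fz < threshold`` holds for at least ``debounce`` frames.
    """
    fz = np.asarray(fz_total, dtype=float)
    if fz.ndim != 1 or len(fz) < 3:
        raise NoStanceDetected("need a 1D series of at least 3 frames")
    above = _runs_at_least(fz >= threshold, debounce)
    if not above.any():
        raise NoStanceDetected(f"vertical GRF never holds >= {threshold} N "
                               f"for {debounce} frames")
    heel_strike = int(np.argmax(above))
    below = _runs_at_least(fz < threshold, debounce)
    below[: heel_strike + 1] = False
    if not below.any():
        raise NoStanceDetected("foot never unloads after heel strike")
    toe_off = int(np.argmax(below))
    return heel_strike, toe_off


def subdivide_stance(heel_y, met1_y, stance, height_threshold: float = 20.0) -> StancePhases:
    """Split [heel_strike, toe_off) at the 20 mm marker-height crossings.

    foot_flat is the first stance frame where the first-metatarsal marker
    height drops below ``height_threshold``; heel_off the first later frame
    where the heel marker height re-rises to at least the threshold.
    Marker heights are used as-is (marker centre above the lab floor).
    """
    heel_strike, toe_off = stance
    heel_y = np.asarray(heel_y, dtype=float)
    met1_y = np.asarray(met1_y, dtype=float)
    low = np.flatnonzero(met1_y[heel_strike:toe_off] < height_threshold)
    if len(low) == 0:
        raise NoFootFlat(f"MET1 never below {height_threshold} mm in stance")
    foot_flat = heel_strike + int(low[0])
    rise = np.flatnonzero(heel_y[foot_flat + 1:toe_off] >= height_threshold)
    if len(rise) == 0:
        raise NoHeelOff(f"heel never re-rises above {height_threshold} mm")
    heel_off = foot_flat + 1 + int(rise[0])
    return StancePhases(heel_strike, foot_flat, heel_off, toe_off)


def normalize_time(stance, rate: float | None = None) -> np.ndarray:
    """Percent-of-stance for each stance frame: affine map onto [0, 100].

    A stance of n frames maps frame i (0-based within stance) to
    ``100 * i / (n - 1)``, so an 101-frame stance yields 0, 1, ..., 100.
    ``rate`` is accepted for interface symmetry but does not affect the
    normalized axis.
    """
    heel_strike, toe_off = stance
    n = toe_off - heel_strike
    if n <= 0:
        raise NoStanceDetected("empty stance range")
    if n == 1:
        return np.zeros(1)
    return 100.0 * np.arange(n) / (n - 1)
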