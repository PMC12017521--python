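"""Model-accuracy utilities: curve similarity (R^2) and pattern labels.

Force-displacement (or moment-angle) curves from different studies live on
different scales, so before comparison both curves are resampled by linear
interpolation onto a common normalized abscissa grid and their ordinates
are min-max scaled to [0, 1]. R^2 = 1 - SS_res/SS_tot is then computed with
one curve as reference; the measure is asymmetric in that choice, so
callers typically report both orderings.

The stiff/compliant pattern classifier labels four stance windows (early
heel contact, plantar contact, early push-off, late push-off) by comparing
each window's fitted slope against 3x the plantar-contact slope — the
compliant reference within the trial.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DegenerateFit, DegenerateReference

#: stiff/compliant threshold: multiple of the plantar-contact slope
STIFF_RATIO = 3.0
#: fallback absolute threshold (kN/mm) when the compliant reference is <= 0
STIFF_FALLBACK_KN_PER_MM = 0.02


@dataclass
class Curve2D:
    """An ordered 2D curve (e.g. arch load versus displacement)."""

    x: np.ndarray
    y: np.ndarray
    label: str = ""

    def __post_init__(self):
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if self.x.ndim != 1 or self.x.shape != self.y.shape or len(self.x) < 2:
            raise DegenerateFit("curve needs matching 1D x/y of length >= 2")
        if np.any(np.diff(self.x) < 0):
            raise DegenerateFit("curve abscissa must be non-decreasing")


def _normalize(curve: Curve2D, n_points: int):
    """Resample onto n_points equally spaced normalized abscissae and
    min-max scale the ordinate to [0, 1]."""
    xr = np.ptp(curve.x)
    if xr == 0:
        raise DegenerateFit(f"curve {curve.label!r} has zero abscissa span")
    xs = (curve.x - curve.x.min()) / xr
    grid = np.linspace(0.0, 1.0, n_points)
    y = np.interp(grid, xs, curve.y)
    yr = np.ptp(y)
    if yr == 0:
        return y * 0.0
    return (y - y.min()) / yr


def curve_r2(a: Curve2D, b: Curve2D, n_points: int = 101) -> float:
    """Coefficient of determination between two aligned, scaled curves.

    ``b`` is the reference, ``a`` the prediction. Both are interpolated to
    ``n_points`` on a normalized abscissa and min-max scaled, which makes
    the result invariant to affine rescaling of either axis.
    """
    ya = _normalize(a, n_points)
    yb = _normalize(b, n_points)
    ss_tot = float(np.sum((yb - yb.mean()) ** 2))
    if ss_tot == 0:
        raise DegenerateReference(f"reference curve {b.label!r} is constant")
    ss_res = float(np.sum((ya - yb) ** 2))
    return 1.0 - ss_res / ss_tot


def classify_pattern(slopes_kn_per_mm) -> list:
    """Label four stance-window slopes as 'stiff' or 'compliant'.

    ``slopes_kn_per_mm`` are the fitted slopes over (early heel contact,
    plantar contact, early push-off, late push-off) in stance order. A
    window is stiff when its slope >= 3x the plantar-contact slope; when
    that compliant reference is non-positive, a fixed 0.02 kN/mm threshold
    is used instead.
    """
    s = np.asarray(slopes_kn_per_mm, dtype=float)
    if s.shape != (4,) or not np.all(np.isfinite(s)):
        raise DegenerateFit("need four finite window slopes")
    ref = s[1]
    threshold = STIFF_RATIO * ref if ref > 0 else STIFF_FALLBACK_KN_PER_MM
    return ["stiff" if v >= threshold else "compliant" for v in s]


def pattern_slopes(stiff_series, phases, hc_fraction: float = 0.5) -> np.ndarray:
    """Fitted slopes over the four classification windows of one trial."""
    from .stiffness import classification_windows, fit_phase_stiffness
    wins = classification_windows(phases, hc_fraction=hc_fraction)
    return np.array([
        fit_phase_stiffness(stiff_series.f_along_h, stiff_series.h, w)[0]
        for w in wins])
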