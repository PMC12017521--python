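"""Filtering, synchronization, and projection onto the arch plane.

The model is two-dimensional: everything is expressed in the vertical plane
of the medial longitudinal arch (MLA). Per frame, the in-plane x axis is the
horizontal unit vector from the posterior calcaneus marker toward the first
metatarsal head, and the y axis is world-vertical. Out-of-plane components
are discarded, matching the planar model's neglect of them.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import BadWindow, ClockMismatch, DegenerateFrame

#: Controlled vocabulary of foot landmarks.
LANDMARKS = ("CAL", "MET1", "NAV", "HLX", "ANK", "SHK")


@dataclass
class PlanarTrial:
    """A trial expressed in the 2D arch plane at the marker rate.

    Attributes
    ----------
    markers : dict[str, np.ndarray]
        Per landmark an (N, 2) array of (x, y) positions in mm; x is the
        anteroposterior in-plane axis, y is world-vertical.
    plate_f : np.ndarray
        (n_plates, N, 2) in-plane plate forces, N: column 0 the horizontal
        in-plane friction Ff, column 1 the vertical force FGR.
    plate_cop : np.ndarray
        (n_plates, N) in-plane (x) centre-of-pressure coordinate, mm.
    rate : float
        Common sampling rate, Hz.
    """

    markers: dict = field(default_factory=dict)
    plate_f: np.ndarray | None = None
    plate_cop: np.ndarray | None = None
    rate: float = 100.0

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.markers.values())))


def moving_average(series, window: int):
    """Centered moving mean with shrinking symmetric edge windows.

    At frame i the window is the largest symmetric span of at most
    ``window`` samples fully inside the series, so the output has the same
    length as the input and a constant series is preserved exactly.

    Parameters
    ----------
    series : array-like, shape (N,) or (N, C)
        Input samples; 2D input is filtered column-wise.
    window : int
        Odd window length, ``1 <= window <= N``. ``window == 1`` is the
        identity.
    """
    x = np.asarray(series, dtype=float)
    n = x.shape[0]
    if window < 1 or window % 2 == 0:
        raise BadWindow(f"window must be odd and positive, got {window}")
    if window > n:
        raise BadWindow(f"window {window} exceeds series length {n}")
    if window == 1:
        return x.copy()
    half = window // 2
    # cumulative-sum implementation; edge windows shrink symmetrically
    zero = np.zeros((1,) + x.shape[1:])
    cs = np.concatenate([zero, np.cumsum(x, axis=0)], axis=0)
    idx = np.arange(n)
    h = np.minimum(half, np.minimum(idx, n - 1 - idx))
    lo, hi = idx - h, idx + h + 1
    out = (cs[hi] - cs[lo]) / (hi - lo).reshape((-1,) + (1,) * (x.ndim - 1))
    return out


def downsample_grf(forces, factor: int, pre_window: int | None = None):
    """Decimate force-plate samples to the marker rate.

    An anti-alias moving average of length ``factor`` (rounded up to odd)
    is applied, then every ``factor``-th sample (starting at index 0) is
    kept, so sample k of the output is simultaneous with marker frame k.

    Parameters
    ----------
    forces : array-like, shape (M,) or (M, C)
    factor : int
        ``grf_rate / marker_rate``; must be a positive integer.
    pre_window : int, optional
        Extra smoothing window applied before decimation (the general GRF
        filter); None skips it.
    """
    if not float(factor).is_integer() or factor < 1:
        raise ClockMismatch(f"rate ratio must be a positive integer, got {factor}")
    factor = int(factor)
    x = np.asarray(forces, dtype=float)
    if pre_window is not None and pre_window > 1:
        x = moving_average(x, pre_window)
    w = factor if factor % 2 == 1 else factor + 1
    if factor > 1:
        x = moving_average(x, min(w, x.shape[0] if x.shape[0] % 2 == 1 else x.shape[0] - 1))
    return x[::factor]


def _plane_axes(cal_xyz: np.ndarray, met1_xyz: np.ndarray, vertical_axis: int,
                per_frame: bool, min_horiz: float = 1.0):
    """Per-frame horizontal unit vector x-hat of the MLA plane.

    Returns an (N, 3) array of horizontal unit vectors. Raises
    :class:`DegenerateFrame` when the horizontal calcaneus-to-metatarsal
    component falls below ``min_horiz`` mm.
    """
    d = met1_xyz - cal_xyz
    d = d.copy()
    d[:, vertical_axis] = 0.0
    norm = np.linalg.norm(d, axis=1)
    if not per_frame:
        mean_d = d.mean(axis=0)
        mnorm = np.linalg.norm(mean_d)
        if mnorm < min_horiz:
            raise DegenerateFrame("stance-averaged foot axis is vertical")
        return np.tile(mean_d / mnorm, (len(d), 1))
    if np.any(norm < min_horiz):
        bad = int(np.argmin(norm))
        raise DegenerateFrame(
            f"frame {bad}: horizontal CAL->MET1 component {norm[bad]:.3g} mm < {min_horiz} mm"
        )
    return d / norm[:, None]


def project_to_mla_plane(trial, marker_window: int = 7, grf_window: int = 21,
                         plane: str = "per_frame") -> PlanarTrial:
    """Filter, synchronize, and project a trial onto the 2D MLA plane.

    Markers are smoothed with ``marker_window``, plate records with
    ``grf_window`` and decimated to the marker rate, then every marker
    position, force vector, and centre of pressure is expressed as
    (v . x-hat, v . y-hat), where x-hat is the horizontal unit vector along
    CAL->MET1 (recomputed each frame by default) and y-hat is world-vertical.
    Vertical components are preserved exactly by construction.
    """
    if plane not in ("per_frame", "fixed"):
        raise BadWindow(f"plane must be 'per_frame' or 'fixed', got {plane!r}")
    vert = trial.markers.vertical_axis
    filt = {name: moving_average(trial.markers.positions[name], marker_window)
            for name in trial.markers.positions}
    factor = int(round(trial.meta.grf_rate / trial.meta.marker_rate))
    if abs(trial.meta.grf_rate / trial.meta.marker_rate - factor) > 1e-9:
        raise ClockMismatch(
            f"grf_rate {trial.meta.grf_rate} not an integer multiple of "
            f"marker_rate {trial.meta.marker_rate}")

    xhat = _plane_axes(filt["CAL"], filt["MET1"], vert, plane == "per_frame")
    yhat = np.zeros_like(xhat)
    yhat[:, vert] = 1.0

    # horizontal reference: first-frame calcaneus position, so the planar
    # frame is invariant to horizontal translation of the capture volume
    ref = filt["CAL"][0].copy()
    ref[vert] = 0.0

    n = len(xhat)
    markers2d = {}
    for name, pos in filt.items():
        markers2d[name] = np.stack(
            [np.einsum("ij,ij->i", pos - ref, xhat), pos[:, vert]], axis=1)

    n_plates = trial.plates.forces.shape[0]
    plate_f = np.zeros((n_plates, n, 2))
    plate_cop = np.zeros((n_plates, n))
    for p in range(n_plates):
        f = downsample_grf(trial.plates.forces[p], factor, pre_window=grf_window)
        cop = downsample_grf(trial.plates.cop[p], factor, pre_window=grf_window)
        m = min(len(f), n)
        if abs(len(f) - n) > 1:
            raise ClockMismatch(
                f"plate {p}: {len(f)} decimated samples vs {n} marker frames")
        plate_f[p, :m, 0] = np.einsum("ij,ij->i", f[:m], xhat[:m])
        plate_f[p, :m, 1] = f[:m, vert]
        plate_cop[p, :m] = np.einsum("ij,ij->i", cop[:m] - ref, xhat[:m])
    return PlanarTrial(markers=markers2d, plate_f=plate_f, plate_cop=plate_cop,
                       rate=trial.meta.marker_rate)
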