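"""Reading and writing trials and results.

File dialects
-------------
Marker CSV (wide): header ``time,CAL_x,CAL_y,CAL_z,MET1_x,...``; time in
seconds, positions in mm, world frame with the **z axis vertical**.

Force CSV (long): header ``time,plate,Fx,Fy,Fz,COPx,COPy,COPz``; one row
per plate per sample, plate indices 0..n-1, forces in N, CoP in mm.

Metadata: YAML ``key: value`` text with keys ``subject_id, sex,
body_mass_kg, truncated_foot_length_mm, marker_rate_hz, grf_rate_hz``.

Units are fixed internally: mm, N, kg, s; stiffness is reported in kN/mm.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import BadMeta, ClockMismatch, MissingMarker, ParseError
from .preprocess import LANDMARKS

VERTICAL_AXIS = 2  # world z


@dataclass(frozen=True)
class TrialMeta:
    """Subject and acquisition metadata for one walking trial."""

    subject_id: str
    sex: str
    body_mass: float               # kg
    truncated_foot_length: float   # mm, posterior heel to first metatarsal head
    marker_rate: float = 100.0     # Hz
    grf_rate: float = 1000.0       # Hz

    def __post_init__(self):
        if self.body_mass <= 0:
            raise BadMeta(f"body_mass must be > 0, got {self.body_mass}")
        if self.truncated_foot_length <= 0:
            raise BadMeta("truncated_foot_length must be > 0")
        if self.marker_rate <= 0 or self.grf_rate < self.marker_rate:
            raise BadMeta("need grf_rate >= marker_rate > 0")
        ratio = self.grf_rate / self.marker_rate
        if abs(ratio - round(ratio)) > 1e-9:
            raise BadMeta("grf_rate must be an integer multiple of marker_rate")
        if self.sex not in ("F", "M", "other"):
            raise BadMeta(f"sex must be F/M/other, got {self.sex!r}")

    @property
    def body_weight(self) -> float:
        """Body weight in N (g = 9.81 m/s^2)."""
        return self.body_mass * 9.81


@dataclass
class MarkerSet:
    """3D trajectories (mm, world frame) of the six foot landmarks."""

    positions: dict = field(default_factory=dict)  # name -> (N, 3)
    vertical_axis: int = VERTICAL_AXIS

    def __post_init__(self):
        unknown = set(self.positions) - set(LANDMARKS)
        if unknown:
            raise MissingMarker(f"unknown landmark name(s): {sorted(unknown)}")
        missing = set(LANDMARKS) - set(self.positions)
        if missing:
            raise MissingMarker(f"missing landmark(s): {sorted(missing)}")
        lengths = {name: len(p) for name, p in self.positions.items()}
        if len(set(lengths.values())) != 1:
            raise ClockMismatch(f"trajectory lengths differ: {lengths}")
        for name, p in self.positions.items():
            if not np.all(np.isfinite(p)):
                raise ParseError(f"non-finite samples in {name} after gap handling")

    @property
    def n_frames(self) -> int:
        return len(next(iter(self.positions.values())))


@dataclass
class ForcePlateSeries:
    """World-frame forces (N) and centres of pressure (mm) for the plates."""

    forces: np.ndarray   # (n_plates, M, 3)
    cop: np.ndarray      # (n_plates, M, 3)

    def __post_init__(self):
        if self.forces.shape != self.cop.shape:
            raise ClockMismatch("force and CoP arrays must share a shape")

    @property
    def n_samples(self) -> int:
        return self.forces.shape[1]


@dataclass
class Trial:
    """One walking trial: markers + plates + metadata on a common clock."""

    meta: TrialMeta
    markers: MarkerSet
    plates: ForcePlateSeries

    def __post_init__(self):
        factor = int(round(self.meta.grf_rate / self.meta.marker_rate))
        expected = self.markers.n_frames * factor
        if abs(self.plates.n_samples - expected) > factor:
            raise ClockMismatch(
                f"{self.plates.n_samples} plate samples vs {expected} expected "
                f"from {self.markers.n_frames} marker frames x {factor}")


def interpolate_gaps(values: np.ndarray, max_gap: int = 5) -> np.ndarray:
    """Linearly fill runs of <= ``max_gap`` NaN samples; longer gaps raise."""
    out = np.array(values, dtype=float)
    for c in range(out.shape[1]) if out.ndim == 2 else [None]:
        col = out[:, c] if c is not None else out
        bad = np.isnan(col)
        if not bad.any():
            continue
        runs = np.diff(np.flatnonzero(np.diff(np.concatenate(
            [[0], bad.view(np.int8), [0]]))).reshape(-1, 2), axis=1)
        if runs.size and runs.max() > max_gap:
            raise ParseError(f"marker gap longer than {max_gap} samples")
        good = ~bad
        col[bad] = np.interp(np.flatnonzero(bad), np.flatnonzero(good), col[good])
    return out


def _read_numeric_csv(path) -> pd.DataFrame:
    try:
        df = pd.read_csv(path)
    except Exception as exc:  # malformed file
        raise ParseError(f"{path}: {exc}") from exc
    return df


def read_meta(path) -> TrialMeta:
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ParseError(f"{path}: metadata must be key: value pairs")
    try:
        return TrialMeta(
            subject_id=str(raw["subject_id"]),
            sex=str(raw.get("sex", "other")),
            body_mass=float(raw["body_mass_kg"]),
            truncated_foot_length=float(raw["truncated_foot_length_mm"]),
            marker_rate=float(raw.get("marker_rate_hz", 100.0)),
            grf_rate=float(raw.get("grf_rate_hz", 1000.0)),
        )
    except KeyError as exc:
        raise BadMeta(f"{path}: missing metadata key {exc}") from exc
    except (TypeError, ValueError) as exc:
        raise ParseError(f"{path}: {exc}") from exc


def read_trial(markers_path, forces_path, meta_path) -> Trial:
    """Load and validate a trial from the CSV dialects above."""
    meta = read_meta(meta_path)
    mdf = _read_numeric_csv(markers_path)
    positions = {}
    for name in LANDMARKS:
        cols = [f"{name}_x", f"{name}_y", f"{name}_z"]
        if not all(c in mdf.columns for c in cols):
            raise MissingMarker(f"{markers_path}: missing column(s) for {name}")
        arr = mdf[cols].to_numpy()
        try:
            arr = arr.astype(float)
        except ValueError as exc:
            raise ParseError(f"{markers_path}: non-numeric cell in {name}") from exc
        positions[name] = interpolate_gaps(arr)
    markers = MarkerSet(positions=positions)

    fdf = _read_numeric_csv(forces_path)
    required = ["time", "plate", "Fx", "Fy", "Fz", "COPx", "COPy", "COPz"]
    if not all(c in fdf.columns for c in required):
        raise ParseError(f"{forces_path}: expected columns {required}")
    plates = sorted(fdf["plate"].unique())
    per = []
    for p in plates:
        sub = fdf[fdf["plate"] == p].sort_values("time")
        try:
            per.append((sub[["Fx", "Fy", "Fz"]].to_numpy(dtype=float),
                        sub[["COPx", "COPy", "COPz"]].to_numpy(dtype=float)))
        except ValueError as exc:
            raise ParseError(f"{forces_path}: non-numeric cell") from exc
    lens = {len(f) for f, _ in per}
    if len(lens) != 1:
        raise ClockMismatch(f"{forces_path}: plates have differing lengths {lens}")
    forces = np.stack([f for f, _ in per])
    cop = np.stack([c for _, c in per])
    return Trial(meta=meta, markers=markers,
                 plates=ForcePlateSeries(forces=forces, cop=cop))


def write_trial(trial: Trial, out_dir) -> dict:
    """Write a trial in the CSV dialects; returns the file paths."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    n = trial.markers.n_frames
    t = np.arange(n) / trial.meta.marker_rate
    cols = {"time": t}
    for name in LANDMARKS:
        for j, ax in enumerate("xyz"):
            cols[f"{name}_{ax}"] = trial.markers.positions[name][:, j]
    markers_path = out / "markers.csv"
    pd.DataFrame(cols).to_csv(markers_path, index=False, float_format="%.10g")

    m = trial.plates.n_samples
    tf = np.arange(m) / trial.meta.grf_rate
    rows = []
    for p in range(trial.plates.forces.shape[0]):
        rows.append(pd.DataFrame({
            "time": tf, "plate": p,
            "Fx": trial.plates.forces[p, :, 0],
            "Fy": trial.plates.forces[p, :, 1],
            "Fz": trial.plates.forces[p, :, 2],
            "COPx": trial.plates.cop[p, :, 0],
            "COPy": trial.plates.cop[p, :, 1],
            "COPz": trial.plates.cop[p, :, 2],
        }))
    forces_path = out / "forces.csv"
    pd.concat(rows).to_csv(forces_path, index=False, float_format="%.10g")

    meta_path = out / "meta.yaml"
    meta_path.write_text(yaml.safe_dump({
        "subject_id": trial.meta.subject_id,
        "sex": trial.meta.sex,
        "body_mass_kg": float(trial.meta.body_mass),
        "truncated_foot_length_mm": float(trial.meta.truncated_foot_length),
        "marker_rate_hz": float(trial.meta.marker_rate),
        "grf_rate_hz": float(trial.meta.grf_rate),
    }))
    return {"markers": markers_path, "forces": forces_path, "meta": meta_path}


def write_results(out_dir, phases, geom, arch_state, stiff, summary,
                  rate: float) -> dict:
    """Write the per-frame TSV and the JSON summary for one analyzed trial."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    hs, to = phases.heel_strike, phases.toe_off
    n = to - hs
    frame = pd.DataFrame({
        "time_s": (np.arange(hs, to)) / rate,
        "pct_stance": 100.0 * np.arange(n) / max(n - 1, 1),
        "phase": arch_state.phase,
        "h_mm": geom.h[hs:to],
        "nnht": geom.nnht[hs:to],
        "fax_n": arch_state.fax,
        "fay_n": arch_state.fay,
        "ma_nmm": arch_state.ma,
        "fal_n": arch_state.fal,
        "f_along_h_n": stiff.f_along_h,
        "k_kn_per_mm": stiff.k,
    })
    series_path = out / "arch_series.tsv"
    frame.to_csv(series_path, sep="\t", index=False, float_format="%.10g")

    summary_path = out / "summary.json"
    payload = summary.as_dict()
    payload["max_fal_n"] = float(np.nanmax(arch_state.fal))
    payload["max_k_kn_per_mm"] = float(np.nanmax(stiff.k))
    payload["n_stance_frames"] = int(n)
    summary_path.write_text(json.dumps(payload, indent=2))
    return {"series": series_path, "summary": summary_path}
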