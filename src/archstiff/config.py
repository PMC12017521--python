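"""Run configuration: one structured mapping with validated defaults."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .dynamics import (FOOT_MASS_FRACTION, GYRATION_FRACTION, REARFOOT_SHARE,
                       PATensionCurve)
from .errors import BadConfig


@dataclass
class RunConfig:
    """All tunable pipeline parameters with their defaults.

    Filter windows are in samples at the native rate of each stream;
    thresholds follow the stance-detection conventions (30 N vertical GRF,
    20 mm marker height, 3-frame debounce).
    """

    marker_window: int = 7            # marker moving-average window, samples
    grf_window: int = 21              # GRF moving-average window (pre-decimation)
    plane: str = "per_frame"          # 'per_frame' | 'fixed' MLA plane
    grf_threshold_n: float = 30.0
    height_threshold_mm: float = 20.0
    debounce_frames: int = 3
    com_rearfoot_fraction: float = 0.5
    com_forefoot_fraction: float = 0.5
    foot_mass_fraction: float = FOOT_MASS_FRACTION
    rearfoot_share: float = REARFOOT_SHARE
    gyration_fraction: float = GYRATION_FRACTION
    k_window_frames: int = 5          # continuous-stiffness differencing window
    hc_fraction: float = 0.5          # heel-contact fit window (leading share)
    po_fraction: float = 1.0 / 3.0    # push-off fit window (trailing share)
    pa_curve_path: str | None = None  # two-column CSV (percent, BW fraction)
    static_window: tuple = (0, 5)     # frames used for the static arch height
    static_nnht: float | None = None  # overrides the static window when set
    log_level: str = "INFO"

    def __post_init__(self):
        for name in ("grf_threshold_n", "height_threshold_mm",
                     "hc_fraction", "po_fraction"):
            if getattr(self, name) <= 0:
                raise BadConfig(f"{name} must be positive")
        if self.debounce_frames < 1:
            raise BadConfig("debounce_frames must be >= 1")
        for name in ("marker_window", "grf_window", "k_window_frames"):
            v = getattr(self, name)
            if v < 1 or v % 2 == 0:
                raise BadConfig(f"{name} must be odd and positive, got {v}")

    def pa_curve(self) -> PATensionCurve:
        if self.pa_curve_path is None:
            return PATensionCurve()
        df = pd.read_csv(self.pa_curve_path)
        return PATensionCurve(knots=df.to_numpy(dtype=float)[:, :2])

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(raw, dict):
            raise BadConfig(f"{path}: config must be a mapping")
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise BadConfig(f"unknown config key(s): {sorted(unknown)}")
        if "static_window" in raw:
            raw["static_window"] = tuple(raw["static_window"])
        return cls(**raw)
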