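"""Corridor geometry and pipeline configuration.

All numeric constants of the analysis procedures live in :class:`PipelineConfig`
with their standard defaults, so every threshold is overridable from YAML or the
command line while the defaults reproduce the canonical analysis.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import yaml

__all__ = ["CorridorSpec", "PipelineConfig", "DEFAULT_LANDMARKS_CM"]

#: Six visual landmarks along the virtual corridor; the last one marks the
#: approach to the reward zone.
DEFAULT_LANDMARKS_CM: tuple[float, ...] = (110.0, 240.0, 370.0, 500.0, 630.0, 760.0)


@dataclass(frozen=True)
class CorridorSpec:
    """Geometry of the virtual corridor.

    Parameters
    ----------
    length_cm : float
        Total corridor length. Default 832 cm.
    bin_width_cm : float
        Spatial bin width used for all binned analyses. Default 4.24 cm,
        giving ``floor(832 / 4.24) = 196`` bins; the residual track length is
        absorbed by the last bin.
    landmark_centroids_cm : tuple of float
        Along-track centroid positions of the discrete visual landmarks.
    reward_zone_cm : tuple of float
        ``(start, end)`` of the reward zone near the corridor end.
    """

    length_cm: float = 832.0
    bin_width_cm: float = 4.24
    landmark_centroids_cm: tuple[float, ...] = DEFAULT_LANDMARKS_CM
    reward_zone_cm: tuple[float, float] = (760.0, 832.0)

    def __post_init__(self) -> None:
        if self.length_cm <= 0:
            raise ValueError("length_cm must be positive")
        if not (0 < self.bin_width_cm < self.length_cm):
            raise ValueError("bin_width_cm must lie in (0, length_cm)")
        for lm in self.landmark_centroids_cm:
            if not (0 <= lm <= self.length_cm):
                raise ValueError(f"landmark at {lm} cm outside corridor")

    @property
    def n_bins(self) -> int:
        return int(np.floor(self.length_cm / self.bin_width_cm))

    @property
    def bin_centers_cm(self) -> np.ndarray:
        return (np.arange(self.n_bins) + 0.5) * self.bin_width_cm

    def bin_of(self, position_cm: np.ndarray) -> np.ndarray:
        """Map positions to 0-based bin indices; residual length joins the last bin."""
        b = np.floor(np.asarray(position_cm) / self.bin_width_cm).astype(np.int64)
        return np.clip(b, 0, self.n_bins - 1)

    def bin_edges_cm(self, left_bin: int, right_bin: int) -> tuple[float, float]:
        """Physical edges of an inclusive bin interval (right edge clipped)."""
        return (
            left_bin * self.bin_width_cm,
            min((right_bin + 1) * self.bin_width_cm, self.length_cm),
        )


@dataclass
class PipelineConfig:
    """Every tunable constant of the analysis pipeline.

    Defaults are the canonical values used throughout; units are given per
    field. Trace-level constants are in fluorescence a.u. and frames; spatial
    constants in bins or cm.
    """

    # --- trace preprocessing ---
    neuropil_coefficient: float = 0.7        # F = F_raw - c * F_neu
    gate_peak_search_frames: int = 9         # local max between spk and +9 frames
    gate_baseline_window: tuple[int, int] = (30, 20)  # fit frames t-30..t-20
    gate_min_baseline_points: int = 5        # edge rule: reject if fewer available
    global_noise_band: str = "median_fraction"  # or "sd_units"
    global_noise_below: float = 1.5          # band: median*(1-below) .. median*(1+above)
    global_noise_above: float = 0.5
    dff_window: int = 1000                   # rolling-median baseline, samples
    align_window: tuple[int, int] = (50, 150)  # -50..+150 samples around alignment
    align_smooth_points: int = 5             # symmetric moving average
    align_diff_lag: int = 4                  # steepest-rise difference lag

    # --- spatial tuning ---
    speed_threshold_cm_s: float = 4.0        # bins slower than this are masked
    oddeven_min_r: float = 0.25              # odd/even tuning-curve reliability
    n_shuffles: int = 1500                   # circular-shift null iterations
    si_percentile: float = 99.0              # ROI-level Skaggs significance
    local_si_percentile: float = 95.0        # per-field local significance
    peak_height: float = 6.0                 # find_peaks height on tuning curve (a.u./frame)
    peak_rel_height: float = 0.93            # peak_widths relative height
    min_active_lap_fraction: float = 0.30    # PF retention rule

    # --- PFF temporal demarcation / categorization ---
    activity_floor_au: float = 64.0          # inferred activity below this set to 0
    pf_right_extension_bins: int = 5         # forward extension of PF bounds
    min_prior_laps: int = 17                 # formation only after this many laps
    presilence_lap_fraction: float = 0.10    # <=10% of prior laps may be active...
    presilence_activity_fraction: float = 0.01  # ...above 1% of formation-lap mean
    termination_silent_laps: int = 5         # PF ends after this many silent laps
    min_lifetime_laps: int = 9               # exclusion: lifetime < 9 laps
    max_silent_laps: int = 8                 # exclusion: > 8 silent laps
    silent_lap_fraction: float = 0.10        # silent = lap max < 10% of peak
    com_smooth_kernel: int = 3               # running-average kernel on COM series
    drift_p_threshold: float = 0.05          # Spearman significance for drift

    # --- misclassification bootstrap ---
    bootstrap_n_null: int = 1000
    bootstrap_alpha: float = 0.05            # "fewer than 5% of null samples"

    # --- solitary events ---
    solitary_prominence: float = 1.0         # find_peaks prominence on dF/F
    solitary_distance: int = 20              # find_peaks min separation, samples
    solitary_context_laps: int = 5           # +-5 laps
    solitary_context_bins: int = 11          # centered spatial window
    solitary_context_sd: float = 2.0         # context max <= median + 2 SD

    # --- population ---
    switch_contrast_threshold: float = 0.2   # locate_switch minimum block contrast

    # --- width model ---
    min_formation_speed_cm_s: float = 5.0    # slower PFF events excluded
    offset_range_cm: tuple[float, float] = (0.0, 50.0)
    offset_step_cm: float = 1.0
    n_subsample: int = 10000                 # subsample regression resamples

    # --- bookkeeping ---
    seed: int = 0

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        kwargs = {}
        fields = {f.name: f for f in dataclasses.fields(cls)}
        for k, v in d.items():
            if k not in fields:
                raise ValueError(f"unknown config key: {k}")
            if isinstance(v, list):
                v = tuple(v)
            kwargs[k] = v
        return cls(**kwargs)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
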