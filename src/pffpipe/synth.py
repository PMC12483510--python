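"""Synthetic virtual-corridor sessions with implanted, labelled events.

The generator emulates the phenomenology the pipeline is built to detect:
GCaMP6s-like transients at ~31 Hz with neuropil contamination, lap structure
in an 832-cm corridor, and place fields with four kinds of dynamics:

* ``BTSP``: a large, prolonged formation-lap burst centred forward of the
  stable field, followed by smaller per-lap transients shifted backward
  (positive ``com_shift_cm``), optionally with continuous backward COM drift.
* ``NON_BTSP``: a new field appearing with a slightly *smaller* formation-lap
  transient and a bin-aligned constant centre, i.e. neither amplitude gain
  nor backward shift.
* ``PREEXISTING_PF``: a stable field active from the first lap (or over a lap
  range, which is how representational switches are built).
* ``SOLITARY``: one isolated large burst in otherwise silent territory of a
  cell that also owns a BTSP field.

Implant windows are snapped to spatial-bin edges so that the binned
centre of mass of an implanted field is exactly lap-invariant; the only
stochasticity in the classifier's inputs then comes from the explicit noise
parameters rather than from frame-sampling artefacts.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter1d
from scipy.signal import fftconvolve

from .config import CorridorSpec
from .session import BehaviorTrace, GroundTruth, SessionData, SyntheticSession, TruthEvent

__all__ = [
    "SessionConfig",
    "simulate_behavior",
    "implant_events",
    "render_traces",
    "make_session",
    "simulate_untuned_activity",
    "simulate_width_dataset",
    "score_recovery",
]


# ---------------------------------------------------------------------------
# behavior


def simulate_behavior(
    spec: CorridorSpec,
    n_laps: int,
    *,
    mean_speed_cm_s: Optional[float] = None,
    lap_speed_jitter: float = 0.04,
    frame_speed_jitter: float = 0.04,
    slowdown_factor: float = 0.55,
    slowdown_ramp_cm: float = 50.0,
    frame_rate_hz: float = 31.0,
    seed: int = 0,
) -> BehaviorTrace:
    """Simulate running behavior through the virtual corridor.

    The animal runs each lap at a roughly constant speed (session mean drawn
    uniformly from 30-40 cm/s when not given), with small per-lap and smooth
    per-frame speed jitter, and slows down over ``slowdown_ramp_cm`` before
    the reward zone. Reaching the corridor end teleports it back to the
    start; exactly ``n_laps`` teleports occur.
    """
    if n_laps < 1:
        raise ValueError("n_laps must be >= 1")
    rng = np.random.default_rng(seed)
    if mean_speed_cm_s is None:
        mean_speed_cm_s = float(rng.uniform(30.0, 40.0))
    if mean_speed_cm_s <= 0:
        raise ValueError("mean speed must be positive")
    dt = 1.0 / frame_rate_hz
    rz_start = spec.reward_zone_cm[0]

    pos_all, speed_all, lap_all = [], [], []
    for lap in range(1, n_laps + 1):
        lap_speed = mean_speed_cm_s * (1.0 + rng.normal(0.0, lap_speed_jitter))
        lap_speed = max(lap_speed, 1.0)
        pos = 0.0
        ar = 0.0  # smooth AR(1) frame-to-frame jitter
        while pos < spec.length_cm:
            ar = 0.9 * ar + rng.normal(0.0, frame_speed_jitter * np.sqrt(1 - 0.81))
            ramp = 1.0
            if pos > rz_start - slowdown_ramp_cm:
                frac = np.clip((pos - (rz_start - slowdown_ramp_cm)) / slowdown_ramp_cm, 0, 1)
                ramp = 1.0 - (1.0 - slowdown_factor) * frac
            v = max(lap_speed * ramp * (1.0 + ar), 1.0)
            pos_all.append(pos)
            speed_all.append(v)
            lap_all.append(lap)
            pos += v * dt

    n = len(pos_all)
    return BehaviorTrace(
        time_s=np.arange(n) * dt,
        position_cm=np.array(pos_all),
        speed_cm_s=np.array(speed_all),
        lap_index=np.array(lap_all),
        frame_rate_hz=frame_rate_hz,
    )


# ---------------------------------------------------------------------------
# implanting deconvolved activity


def _window_frames(behavior, spec, lap_sl, bin_lo, bin_hi):
    """Frames of one lap whose spatial bin lies in [bin_lo, bin_hi]."""
    bins = spec.bin_of(behavior.position_cm[lap_sl])
    idx = np.flatnonzero((bins >= bin_lo) & (bins <= bin_hi))
    return idx + lap_sl.start


def implant_events(
    behavior: BehaviorTrace,
    truth: GroundTruth,
    spec: CorridorSpec,
    *,
    event_width_bins: int = 2,
    lap_amplitude_jitter: float = 0.05,
    non_btsp_formation_factor: float = 0.8,
    background_rate_hz: float = 0.0,
    background_amp_median_au: float = 30.0,
    background_amp_sigma: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Render ground-truth events into a deconvolved-activity matrix.

    Each event occupies ``event_width_bins`` contiguous spatial bins; every
    frame inside the window on an active lap carries the lap's amplitude.
    Optional spatially untuned background events (amplitudes mostly below
    the 64 a.u. analysis floor) model deconvolution chatter.
    """
    rng = np.random.default_rng(seed)
    n_frames = behavior.n_frames
    n_laps = behavior.n_laps
    act = np.zeros((n_frames, truth.n_rois), dtype=np.float64)
    laps = behavior.lap_slices()
    w = event_width_bins

    def paint(roi, lap, bin_lo, amp):
        bin_lo = int(np.clip(bin_lo, 0, spec.n_bins - w))
        fr = _window_frames(behavior, spec, laps[lap - 1], bin_lo, bin_lo + w - 1)
        if len(fr) == 0:
            return
        if np.any(act[fr, roi] > 0):
            warnings.warn(
                f"overlapping implants on ROI {roi}, lap {lap}; amplitudes summed",
                stacklevel=2,
            )
        act[fr, roi] += amp

    for ev in truth.events:
        if ev.formation_lap > n_laps:
            raise ValueError(
                f"event formation lap {ev.formation_lap} beyond session ({n_laps} laps)"
            )
        if not (0 <= ev.center_cm <= spec.length_cm):
            raise ValueError(f"event center {ev.center_cm} cm outside corridor")
        c_bin = int(spec.bin_of(ev.center_cm))
        end = ev.end_lap if ev.end_lap is not None else n_laps
        end = min(end, n_laps)
        shift_bins = int(round(ev.com_shift_cm / spec.bin_width_cm))

        if ev.kind == "SOLITARY":
            paint(ev.roi_id, ev.formation_lap, c_bin, ev.formation_amplitude_au)
            continue

        if ev.kind == "PREEXISTING_PF":
            for lap in range(ev.formation_lap, end + 1):
                jit = 1.0 + rng.normal(0.0, lap_amplitude_jitter)
                paint(ev.roi_id, lap, c_bin, max(ev.post_amplitude_au * jit, 0.0))
            continue

        if ev.kind == "BTSP":
            # formation burst forward of the stable centre by the COM shift
            paint(ev.roi_id, ev.formation_lap, c_bin + shift_bins, ev.formation_amplitude_au)
            for k, lap in enumerate(range(ev.formation_lap + 1, end + 1), start=1):
                jit = 1.0 + rng.normal(0.0, lap_amplitude_jitter)
                if ev.drift_cm_per_lap > 0:
                    # accelerating backward drift from forward of the
                    # formation location (continuous-drift phenotype)
                    off_cm = 1.5 * ev.drift_cm_per_lap - ev.drift_cm_per_lap * k
                    b = c_bin + shift_bins + int(round(off_cm / spec.bin_width_cm))
                else:
                    b = c_bin
                paint(ev.roi_id, lap, b, max(ev.post_amplitude_au * jit, 0.0))
            continue

        if ev.kind == "NON_BTSP":
            paint(
                ev.roi_id,
                ev.formation_lap,
                c_bin,
                non_btsp_formation_factor * ev.post_amplitude_au,
            )
            for lap in range(ev.formation_lap + 1, end + 1):
                jit = 1.0 + rng.normal(0.0, lap_amplitude_jitter)
                paint(ev.roi_id, lap, c_bin, max(ev.post_amplitude_au * jit, 0.0))
            continue

    if background_rate_hz > 0:
        duration_s = n_frames / behavior.frame_rate_hz
        for roi in range(truth.n_rois):
            n_bg = rng.poisson(background_rate_hz * duration_s)
            if n_bg == 0:
                continue
            fr = rng.integers(0, n_frames, size=n_bg)
            amp = rng.lognormal(np.log(background_amp_median_au), background_amp_sigma, n_bg)
            np.add.at(act[:, roi], fr, amp)

    return act


# ---------------------------------------------------------------------------
# forward fluorescence model


def _double_exp_kernel(rise_s: float, decay_s: float, frame_rate_hz: float) -> np.ndarray:
    """Peak-normalized double-exponential indicator kernel."""
    if rise_s <= 0 or decay_s <= 0:
        raise ValueError("kernel rise/decay constants must be positive")
    t = np.arange(0, 5.0 * decay_s, 1.0 / frame_rate_hz)
    k = np.exp(-t / decay_s) - np.exp(-t / rise_s)
    return k / k.max()


def render_traces(
    deconvolved: np.ndarray,
    *,
    rise_s: float = 0.18,
    decay_s: float = 1.8,
    frame_rate_hz: float = 31.0,
    baseline_au: float = 300.0,
    dff_per_au: float = 0.005,
    noise_sd_au: float = 15.0,
    neuropil_baseline_au: float = 150.0,
    neuropil_sd_au: float = 25.0,
    neuropil_smooth_s: float = 1.0,
    neuropil_mixing: float = 0.7,
    seed: int = 0,
) -> tuple[np.ndarray, np.ndarray]:
    """Forward model from deconvolved activity to raw/neuropil fluorescence.

    ``F_raw = baseline * (1 + dff_per_au * (kernel (*) activity))
    + mixing * F_neu + Gaussian noise``; ``F_neu`` carries a shared,
    low-pass-filtered neuropil signal scaled per ROI. The kernel is a
    GCaMP6s-like double exponential normalized to unit peak, so a single
    deconvolved event of amplitude ``a`` produces a dF/F transient peaking
    at ``dff_per_au * a``.
    """
    if noise_sd_au < 0:
        raise ValueError("noise SD must be non-negative")
    rng = np.random.default_rng(seed)
    n_frames, n_rois = deconvolved.shape
    kernel = _double_exp_kernel(rise_s, decay_s, frame_rate_hz)
    conv = fftconvolve(deconvolved, kernel[:, None], mode="full", axes=0)[:n_frames]
    conv = np.maximum(conv, 0.0)

    shared = rng.normal(0.0, 1.0, n_frames)
    shared = gaussian_filter1d(shared, sigma=neuropil_smooth_s * frame_rate_hz)
    sd = shared.std()
    shared = shared / sd * neuropil_sd_au if sd > 0 else shared
    roi_scale = rng.uniform(0.8, 1.2, n_rois)
    F_neu = neuropil_baseline_au + np.outer(shared, roi_scale)

    F_raw = (
        baseline_au * (1.0 + dff_per_au * conv)
        + neuropil_mixing * F_neu
        + rng.normal(0.0, noise_sd_au, (n_frames, n_rois))
    )
    return F_raw, F_neu


# ---------------------------------------------------------------------------
# full session


@dataclass
class SessionConfig:
    """Defaults of the synthetic study conditions.

    A default session has 200 ROIs over 60 laps of the 832-cm corridor at
    ~31 Hz, with 15 BTSP-like, 12 non-BTSP-like, 4 drifting, and 40
    pre-existing place fields plus 8 solitary transients on BTSP cells;
    remaining ROIs carry only background chatter.
    """

    n_rois: int = 200
    n_laps: int = 60
    corridor: CorridorSpec = field(default_factory=CorridorSpec)
    frame_rate_hz: float = 31.0
    mean_speed_cm_s: Optional[float] = None   # None: drawn from U(30, 40)

    n_btsp: int = 15
    n_non_btsp: int = 12
    n_drift: int = 4
    n_preexisting: int = 40
    n_solitary: int = 8
    switch_lap: Optional[int] = None

    formation_lap_range: tuple[int, int] = (19, 40)
    formation_amp_range_au: tuple[float, float] = (400.0, 800.0)
    post_amp_range_au: tuple[float, float] = (150.0, 300.0)
    com_shift_bins_range: tuple[int, int] = (1, 3)
    drift_cm_per_lap: float = 3.0
    solitary_amp_factor: float = 1.5
    center_bin_range: tuple[int, int] = (15, 178)

    event_width_bins: int = 2
    lap_amplitude_jitter: float = 0.05
    background_rate_hz: float = 0.005

    # forward-model parameters
    rise_s: float = 0.18
    decay_s: float = 1.8
    baseline_au: float = 300.0
    dff_per_au: float = 0.005
    noise_sd_au: float = 15.0
    neuropil_sd_au: float = 25.0

    def __post_init__(self) -> None:
        n_pf = self.n_btsp + self.n_non_btsp + self.n_drift + self.n_preexisting
        if self.switch_lap is not None:
            n_pf += self.n_preexisting  # second map
        if n_pf > self.n_rois:
            raise ValueError(
                f"config requests {n_pf} place-field ROIs but only {self.n_rois} ROIs"
            )
        if self.n_solitary > self.n_btsp:
            raise ValueError("solitary events are implanted on BTSP ROIs")
        if self.formation_lap_range[1] > self.n_laps:
            raise ValueError(
                f"formation_lap_range {self.formation_lap_range} exceeds "
                f"n_laps={self.n_laps}"
            )


def _draw_truth(cfg: SessionConfig, rng: np.random.Generator) -> GroundTruth:
    spec = cfg.corridor
    events: list[TruthEvent] = []
    roi = 0

    def rand_center() -> float:
        b = int(rng.integers(cfg.center_bin_range[0], cfg.center_bin_range[1] + 1))
        return float(b * spec.bin_width_cm)

    def rand_flap() -> int:
        return int(rng.integers(cfg.formation_lap_range[0], cfg.formation_lap_range[1] + 1))

    btsp_rois: list[int] = []
    for _ in range(cfg.n_btsp):
        shift_bins = int(rng.integers(*cfg.com_shift_bins_range, endpoint=True))
        events.append(
            TruthEvent(
                roi_id=roi,
                kind="BTSP",
                formation_lap=rand_flap(),
                center_cm=rand_center(),
                formation_amplitude_au=float(rng.uniform(*cfg.formation_amp_range_au)),
                post_amplitude_au=float(rng.uniform(*cfg.post_amp_range_au)),
                com_shift_cm=shift_bins * spec.bin_width_cm,
            )
        )
        btsp_rois.append(roi)
        roi += 1

    for _ in range(cfg.n_non_btsp):
        post = float(rng.uniform(*cfg.post_amp_range_au))
        events.append(
            TruthEvent(
                roi_id=roi,
                kind="NON_BTSP",
                formation_lap=rand_flap(),
                center_cm=rand_center(),
                formation_amplitude_au=0.8 * post,  # matches the implant rule
                post_amplitude_au=post,
            )
        )
        roi += 1

    for _ in range(cfg.n_drift):
        flap = rand_flap()
        events.append(
            TruthEvent(
                roi_id=roi,
                kind="BTSP",
                formation_lap=flap,
                center_cm=rand_center(),
                formation_amplitude_au=float(rng.uniform(*cfg.formation_amp_range_au)),
                post_amplitude_au=float(rng.uniform(*cfg.post_amp_range_au)),
                com_shift_cm=0.0,
                drift_cm_per_lap=cfg.drift_cm_per_lap,
                end_lap=min(flap + 18, cfg.n_laps),
            )
        )
        roi += 1

    n_maps = 2 if cfg.switch_lap is not None else 1
    for m in range(n_maps):
        for _ in range(cfg.n_preexisting):
            if cfg.switch_lap is None:
                start, end = 1, cfg.n_laps
            elif m == 0:
                start, end = 1, cfg.switch_lap - 1
            else:
                start, end = cfg.switch_lap, cfg.n_laps
            events.append(
                TruthEvent(
                    roi_id=roi,
                    kind="PREEXISTING_PF",
                    formation_lap=start,
                    center_cm=rand_center(),
                    formation_amplitude_au=0.0,
                    post_amplitude_au=float(rng.uniform(*cfg.post_amp_range_au)),
                    end_lap=end,
                )
            )
            roi += 1

    # solitary bursts on BTSP cells, far from the cell's field
    for i in range(cfg.n_solitary):
        host = next(e for e in events if e.roi_id == btsp_rois[i] and e.kind == "BTSP")
        host_bin = int(spec.bin_of(host.center_cm))
        while True:
            b = int(rng.integers(cfg.center_bin_range[0], cfg.center_bin_range[1] + 1))
            if abs(b - host_bin) >= 20:
                break
        events.append(
            TruthEvent(
                roi_id=host.roi_id,
                kind="SOLITARY",
                formation_lap=int(rng.integers(19, cfg.n_laps - 5)),
                center_cm=float(b * spec.bin_width_cm),
                formation_amplitude_au=cfg.solitary_amp_factor
                * host.formation_amplitude_au,
                post_amplitude_au=0.0,
            )
        )

    return GroundTruth(n_rois=cfg.n_rois, events=events, switch_lap=cfg.switch_lap)


def make_session(config: SessionConfig, seed: int = 0) -> SyntheticSession:
    """Build a fully populated synthetic session, deterministic in (config, seed)."""
    ss = np.random.SeedSequence(seed)
    s_beh, s_truth, s_impl, s_rend = [int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(4)]

    behavior = simulate_behavior(
        config.corridor,
        config.n_laps,
        mean_speed_cm_s=config.mean_speed_cm_s,
        frame_rate_hz=config.frame_rate_hz,
        seed=s_beh,
    )
    truth = _draw_truth(config, np.random.default_rng(s_truth))
    deconvolved = implant_events(
        behavior,
        truth,
        config.corridor,
        event_width_bins=config.event_width_bins,
        lap_amplitude_jitter=config.lap_amplitude_jitter,
        background_rate_hz=config.background_rate_hz,
        seed=s_impl,
    )
    F_raw, F_neu = render_traces(
        deconvolved,
        rise_s=config.rise_s,
        decay_s=config.decay_s,
        frame_rate_hz=config.frame_rate_hz,
        baseline_au=config.baseline_au,
        dff_per_au=config.dff_per_au,
        noise_sd_au=config.noise_sd_au,
        neuropil_sd_au=config.neuropil_sd_au,
        seed=s_rend,
    )
    return SessionData(
        behavior=behavior,
        F_raw=F_raw,
        F_neu=F_neu,
        deconvolved=deconvolved,
        corridor=config.corridor,
        truth=truth,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# auxiliary simulators used for calibration studies


def simulate_untuned_activity(
    behavior: BehaviorTrace,
    n_cells: int,
    *,
    rate_hz: float = 0.05,
    amp_median_au: float = 150.0,
    amp_sigma: float = 0.5,
    seed: int = 0,
) -> np.ndarray:
    """Spatially untuned cells: events uniform in time, lognormal amplitudes."""
    rng = np.random.default_rng(seed)
    n_frames = behavior.n_frames
    duration_s = n_frames / behavior.frame_rate_hz
    act = np.zeros((n_frames, n_cells))
    for c in range(n_cells):
        n_ev = rng.poisson(rate_hz * duration_s)
        fr = rng.integers(0, n_frames, size=n_ev)
        amp = rng.lognormal(np.log(amp_median_au), amp_sigma, n_ev)
        np.add.at(act[:, c], fr, amp)
    return act


def simulate_width_dataset(
    n: int,
    r2_speed: float = 0.5,
    *,
    beta_speed: float = 0.8,
    mean_speed: float = 35.0,
    sd_speed: float = 10.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Widths linear in speed with a chosen population R^2; cue distance is noise."""
    if not (0 < r2_speed < 1):
        raise ValueError("r2_speed must lie in (0, 1)")
    rng = np.random.default_rng(seed)
    speed = np.clip(rng.normal(mean_speed, sd_speed, n), 5.0, None)
    signal = beta_speed * speed
    noise_sd = np.sqrt(np.var(signal) * (1 - r2_speed) / r2_speed)
    width = 10.0 + signal + rng.normal(0.0, noise_sd, n)
    cue = rng.uniform(0.0, 60.0, n)
    return pd.DataFrame({"width_cm": width, "speed_cm_s": speed, "cue_distance_cm": cue})


# ---------------------------------------------------------------------------
# scoring detected events against ground truth


def score_recovery(
    truth: GroundTruth,
    events: pd.DataFrame,
    tol_laps: int = 1,
) -> dict:
    """Score pipeline output against implanted BTSP / NON_BTSP ground truth.

    A truth event counts as *detected* if the pipeline reports a formation
    event on the same ROI within ``tol_laps`` laps, and as *correct* if its
    category also matches. Drifting implants (``drift_cm_per_lap > 0``) are
    scored separately as expected ``EXCLUDED_DRIFT``.
    Balanced accuracy is the mean of the BTSP and NON_BTSP recalls, where a
    recall counts events both detected and correctly labelled.
    """
    rows = []
    for ev in truth.events:
        if ev.kind not in ("BTSP", "NON_BTSP"):
            continue
        expected = "EXCLUDED_DRIFT" if ev.drift_cm_per_lap > 0 else ev.kind
        hit = events[events.roi_id == ev.roi_id] if len(events) else events
        detected, correct, lap_err = False, False, np.nan
        if len(hit):
            err = (hit.formation_lap - ev.formation_lap).abs()
            j = err.idxmin()
            lap_err = int(err.loc[j])
            detected = lap_err <= tol_laps
            correct = detected and (hit.loc[j, "category"] == expected)
        rows.append(
            dict(roi_id=ev.roi_id, expected=expected, detected=detected,
                 correct=correct, lap_error=lap_err)
        )
    df = pd.DataFrame(rows)
    out = {"per_event": df}
    for kind in ("BTSP", "NON_BTSP", "EXCLUDED_DRIFT"):
        sub = df[df.expected == kind]
        out[f"recall_{kind}"] = float(sub.correct.mean()) if len(sub) else np.nan
        out[f"detection_{kind}"] = float(sub.detected.mean()) if len(sub) else np.nan
    out["balanced_accuracy"] = float(
        np.mean([out["recall_BTSP"], out["recall_NON_BTSP"]])
    )
    out["detection_rate"] = float(
        df[df.expected.isin(["BTSP", "NON_BTSP"])].detected.mean()
    )
    return out
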