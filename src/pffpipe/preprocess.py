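"""Trace preprocessing: neuropil correction, noise gating, dF/F, alignment.

The gate keeps a deconvolved event only if the fluorescence transient that
accompanies it exceeds both a local noise estimate (RMSE of a linear baseline
fit over frames t-30..t-20) and a global one (SD of the corrected trace within
a band around its median). This removes deconvolution chatter that has no
visible fluorescence correlate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .config import PipelineConfig

__all__ = [
    "neuropil_correct",
    "global_noise_sd",
    "gate_inferred_events",
    "compute_dff",
    "DffMatrix",
    "align_and_measure_transients",
    "TransientAlignment",
]


def _as_columns(F: np.ndarray) -> np.ndarray:
    """View a 1-D trace as a frames x 1 matrix."""
    F = np.asarray(F, dtype=np.float64)
    return F[:, None] if F.ndim == 1 else F


def neuropil_correct(
    F_raw: np.ndarray, F_neu: np.ndarray, coefficient: float = 0.7
) -> np.ndarray:
    """Corrected fluorescence ``F = F_raw - coefficient * F_neu`` (elementwise)."""
    F_raw = np.asarray(F_raw, dtype=np.float64)
    F_neu = np.asarray(F_neu, dtype=np.float64)
    if F_raw.shape != F_neu.shape:
        raise ValueError(f"shape mismatch: {F_raw.shape} vs {F_neu.shape}")
    return F_raw - coefficient * F_neu


def global_noise_sd(F: np.ndarray, cfg: Optional[PipelineConfig] = None) -> np.ndarray:
    """Per-ROI global noise: SD of F within a band around the trace median.

    With the default ``median_fraction`` interpretation the band is
    ``[median*(1 - below), median*(1 + above)]``; the ``sd_units``
    alternative uses ``[median - below*SD, median + above*SD]`` with the SD
    of the whole trace.
    """
    cfg = cfg or PipelineConfig()
    F = _as_columns(F)
    out = np.empty(F.shape[1])
    med = np.median(F, axis=0)
    for r in range(F.shape[1]):
        if cfg.global_noise_band == "median_fraction":
            lo = med[r] * (1.0 - cfg.global_noise_below)
            hi = med[r] * (1.0 + cfg.global_noise_above)
        elif cfg.global_noise_band == "sd_units":
            sd = F[:, r].std()
            lo = med[r] - cfg.global_noise_below * sd
            hi = med[r] + cfg.global_noise_above * sd
        else:
            raise ValueError(f"unknown global_noise_band {cfg.global_noise_band!r}")
        sel = F[(F[:, r] >= lo) & (F[:, r] <= hi), r]
        out[r] = sel.std() if len(sel) else 0.0
    return out


def _fmax_at(F: np.ndarray, peak: int) -> float:
    """Mean of the three fluorescence points around a peak, truncated at edges."""
    lo, hi = max(peak - 1, 0), min(peak + 2, len(F))
    return float(F[lo:hi].mean())


def gate_inferred_events(
    F: np.ndarray,
    deconvolved: np.ndarray,
    cfg: Optional[PipelineConfig] = None,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Zero deconvolved events whose fluorescence transient is within noise.

    For each non-zero deconvolved entry at frame ``t`` the transient
    amplitude is ``F_max - F_base`` where ``F_max`` averages three points
    around the local fluorescence maximum in frames ``t..t+9`` and
    ``F_base`` is the prediction of a linear fit over frames ``t-30..t-20``
    evaluated at ``t-20``. The entry is kept iff the amplitude exceeds both
    the fit RMSE (local noise) and the per-ROI global noise SD. Events too
    close to the trace start fall back to the available prefix of the
    baseline window and are rejected when fewer than
    ``cfg.gate_min_baseline_points`` samples remain.

    Returns the gated matrix and a per-candidate report.
    """
    cfg = cfg or PipelineConfig()
    F = np.asarray(F, dtype=np.float64)
    deconvolved = np.asarray(deconvolved, dtype=np.float64)
    if F.shape != deconvolved.shape:
        raise ValueError(f"shape mismatch: {F.shape} vs {deconvolved.shape}")
    n_frames, n_rois = F.shape
    back, front = cfg.gate_baseline_window           # 30, 20
    n_base = back - front + 1                        # 11 samples
    search = cfg.gate_peak_search_frames             # 9

    gated = np.zeros_like(deconvolved)
    sd_glob = global_noise_sd(F, cfg)
    records: list[dict] = []

    # closed-form linear fit over a fixed abscissa 0..n_base-1
    x = np.arange(n_base, dtype=np.float64)
    xm = x.mean()
    xv = ((x - xm) ** 2).sum()

    for roi in range(n_rois):
        cand = np.flatnonzero(deconvolved[:, roi])
        if len(cand) == 0:
            continue
        f = F[:, roi]

        bulk = cand[(cand >= back) & (cand + search < n_frames)]
        edge = np.setdiff1d(cand, bulk)

        if len(bulk):
            # vectorized peak search and baseline fit
            win = f[bulk[:, None] + np.arange(search + 1)]
            peaks = bulk + np.argmax(win, axis=1)
            fmax = np.array([_fmax_at(f, int(p)) for p in peaks])
            base = f[(bulk - back)[:, None] + np.arange(n_base)]
            ym = base.mean(axis=1)
            slope = ((x - xm) * (base - ym[:, None])).sum(axis=1) / xv
            fbase = ym + slope * (x[-1] - xm)        # prediction at t-20
            pred = ym[:, None] + slope[:, None] * (x - xm)
            sd_loc = np.sqrt(((base - pred) ** 2).mean(axis=1))
            amp = fmax - fbase
            ok = (amp > sd_loc) & (amp > sd_glob[roi])
            gated[bulk[ok], roi] = deconvolved[bulk[ok], roi]
            for t, fm, fb, sl, acc in zip(bulk, fmax, fbase, sd_loc, ok):
                records.append(
                    dict(roi_id=roi, frame=int(t), F_max=fm, F_base=fb,
                         SD_local=sl, SD_global=sd_glob[roi], accepted=bool(acc))
                )

        for t in edge:
            hi = min(t + search + 1, n_frames)
            peak = t + int(np.argmax(f[t:hi]))
            fmax = _fmax_at(f, peak)
            lo = max(t - back, 0)
            hi_b = max(t - front + 1, 0)
            seg = f[lo:hi_b]
            if len(seg) < cfg.gate_min_baseline_points:
                records.append(
                    dict(roi_id=roi, frame=int(t), F_max=fmax, F_base=np.nan,
                         SD_local=np.nan, SD_global=sd_glob[roi], accepted=False)
                )
                continue
            xs = np.arange(len(seg), dtype=np.float64)
            sl_, ic_ = np.polyfit(xs, seg, 1)
            pred = sl_ * xs + ic_
            sd_loc = float(np.sqrt(((seg - pred) ** 2).mean()))
            fbase = float(sl_ * xs[-1] + ic_)
            amp = fmax - fbase
            acc = (amp > sd_loc) and (amp > sd_glob[roi])
            if acc:
                gated[t, roi] = deconvolved[t, roi]
            records.append(
                dict(roi_id=roi, frame=int(t), F_max=fmax, F_base=fbase,
                     SD_local=sd_loc, SD_global=sd_glob[roi], accepted=bool(acc))
            )

    report = pd.DataFrame(
        records,
        columns=["roi_id", "frame", "F_max", "F_base", "SD_local", "SD_global", "accepted"],
    )
    return gated, report


@dataclass
class DffMatrix:
    """dF/F with its rolling-median baseline; zeroed where F0 <= 0."""

    dff: np.ndarray
    F0: np.ndarray
    window: int
    invalid: np.ndarray  # boolean mask of frames where F0 <= 0


def compute_dff(F: np.ndarray, window: int = 1000) -> DffMatrix:
    """dF/F against a rolling median of the preceding ``window`` samples.

    Frames earlier than ``window`` use the median of the *following*
    ``window`` samples instead; traces shorter than ``window`` fall back to
    the whole-trace median. Frames with non-positive baseline are flagged
    and set to zero.
    """
    F = _as_columns(F)
    n = F.shape[0]
    df = pd.DataFrame(F)
    if n <= window:
        F0 = np.broadcast_to(np.median(F, axis=0), F.shape).copy()
    else:
        # preceding `window` values, i.e. frames t-window..t-1
        F0 = df.rolling(window).median().shift(1).to_numpy()
        # head: following `window` values, frames t+1..t+window
        rev = df.iloc[::-1].rolling(window).median().shift(1).to_numpy()[::-1]
        head = np.arange(n) < window
        F0[head] = rev[head]
        # frames whose forward window is also incomplete (only possible when
        # n < 2*window+1 near the middle) fall back to the whole-trace median
        nanmask = np.isnan(F0)
        if nanmask.any():
            F0[nanmask] = np.broadcast_to(np.median(F, axis=0), F.shape)[nanmask]
    invalid = F0 <= 0
    dff = np.zeros_like(F)
    ok = ~invalid
    dff[ok] = (F[ok] - F0[ok]) / F0[ok]
    return DffMatrix(dff=dff, F0=F0, window=window, invalid=invalid)


@dataclass
class TransientAlignment:
    """Aligned dF/F windows around transient onsets."""

    windows: np.ndarray          # traces x window-length, NaN-padded
    alignment_index: np.ndarray  # per trace, sample index within its segment
    peak_amplitude: np.ndarray   # per trace
    mean_trace: np.ndarray
    sd_trace: np.ndarray


def steepest_rise_index(trace: np.ndarray, smooth: int = 5, lag: int = 4) -> int:
    """Sample index of the steepest rise: argmax of the lagged difference of
    the symmetrically smoothed trace."""
    s = pd.Series(trace).rolling(smooth, center=True, min_periods=1).mean().to_numpy()
    d = s[lag:] - s[:-lag]
    return int(np.argmax(d)) + lag


def align_and_measure_transients(
    segments: Sequence[np.ndarray],
    has_event: Sequence[bool],
    cfg: Optional[PipelineConfig] = None,
) -> TransientAlignment:
    """Align dF/F segments at transient onset and measure peak amplitudes.

    Segments with an inferred event are aligned at the steepest rise of the
    5-point-smoothed trace (maximum of the 4-sample lagged difference);
    segments without events align at their midpoint. An asymmetric window of
    -50..+150 samples around the alignment point is extracted (NaN-padded at
    segment edges). Each trace's peak amplitude is its value at the index
    where the mean trace peaks, minus the median of its own window.
    """
    cfg = cfg or PipelineConfig()
    pre, post = cfg.align_window
    wlen = pre + post + 1
    if len(segments) == 0:
        return TransientAlignment(
            windows=np.empty((0, wlen)),
            alignment_index=np.empty(0, dtype=int),
            peak_amplitude=np.empty(0),
            mean_trace=np.full(wlen, np.nan),
            sd_trace=np.full(wlen, np.nan),
        )
    windows = np.full((len(segments), wlen), np.nan)
    align_idx = np.zeros(len(segments), dtype=int)
    for i, (seg, ev) in enumerate(zip(segments, has_event)):
        seg = np.asarray(seg, dtype=np.float64)
        a = (
            steepest_rise_index(seg, cfg.align_smooth_points, cfg.align_diff_lag)
            if ev
            else len(seg) // 2
        )
        align_idx[i] = a
        lo, hi = a - pre, a + post + 1
        src_lo, src_hi = max(lo, 0), min(hi, len(seg))
        windows[i, src_lo - lo : src_hi - lo] = seg[src_lo:src_hi]

    mean_trace = np.nanmean(windows, axis=0)
    sd_trace = np.nanstd(windows, axis=0)
    m = int(np.nanargmax(mean_trace))
    with np.errstate(invalid="ignore"):
        peak = windows[:, m] - np.nanmedian(windows, axis=1)
    return TransientAlignment(
        windows=windows,
        alignment_index=align_idx,
        peak_amplitude=peak,
        mean_trace=mean_trace,
        sd_trace=sd_trace,
    )
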