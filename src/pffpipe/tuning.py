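"""Spatial binning, tuning statistics, and place-field demarcation.

Activity is discretized into 4.24-cm bins of the 832-cm corridor (196 bins);
lap/bin cells ridden slower than 4 cm/s are masked out of all tuning
statistics. Spatial selectivity is quantified with Skaggs' information and
tested against a null built by circularly shifting each lap's activity in
time; place fields are demarcated from tuning-curve peaks and validated with
a local version of the same shuffle test.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy.signal import find_peaks, peak_prominences, peak_widths

from .config import CorridorSpec, PipelineConfig
from .session import BehaviorTrace

__all__ = [
    "BinnedSession",
    "bin_session",
    "tuning_curves",
    "oddeven_reliability",
    "skaggs_information",
    "CircularShiftNull",
    "assess_spatial_significance",
    "PlaceField",
    "footprint_candidates",
    "demarcate_place_fields",
]


@dataclass
class BinnedSession:
    """Per-lap, per-bin session summary.

    ``activity[lap, bin, roi]`` is the mean activity per frame (a.u./frame),
    zero where the bin was never visited on that lap; ``occupancy`` counts
    frames; ``speed_ok`` marks cells whose mean running speed reaches the
    threshold (cells with zero occupancy are not ok).
    """

    activity: np.ndarray    # laps x bins x rois
    occupancy: np.ndarray   # laps x bins
    speed_ok: np.ndarray    # laps x bins, bool
    frame_bin: np.ndarray   # per frame
    frame_lap0: np.ndarray  # per frame, 0-based lap
    n_bins: int
    bin_width_cm: float = 4.24

    @property
    def n_laps(self) -> int:
        return self.activity.shape[0]

    @property
    def n_rois(self) -> int:
        return self.activity.shape[2]

    def valid(self) -> np.ndarray:
        """laps x bins mask of cells entering tuning statistics."""
        return self.speed_ok & (self.occupancy > 0)


def bin_session(
    behavior: BehaviorTrace,
    activity: np.ndarray,
    spec: CorridorSpec,
    cfg: Optional[PipelineConfig] = None,
) -> BinnedSession:
    """Bin frame-level activity by lap and spatial bin."""
    cfg = cfg or PipelineConfig()
    activity = np.atleast_2d(np.asarray(activity, dtype=np.float64))
    if activity.shape[0] != behavior.n_frames:
        raise ValueError(
            f"activity has {activity.shape[0]} frames, behavior {behavior.n_frames}"
        )
    n_bins = spec.n_bins
    n_laps = behavior.n_laps
    frame_bin = spec.bin_of(behavior.position_cm)
    frame_lap0 = behavior.lap_index - 1
    idx = frame_lap0 * n_bins + frame_bin
    ncells = n_laps * n_bins

    occupancy = np.bincount(idx, minlength=ncells).astype(np.int64)
    speed_sum = np.bincount(idx, weights=behavior.speed_cm_s, minlength=ncells)
    ind = sp.csr_matrix(
        (np.ones(len(idx)), (idx, np.arange(len(idx)))),
        shape=(ncells, behavior.n_frames),
    )
    sums = np.asarray(ind @ activity)
    with np.errstate(invalid="ignore", divide="ignore"):
        mean_act = np.where(occupancy[:, None] > 0, sums / occupancy[:, None], 0.0)
        mean_speed = np.where(occupancy > 0, speed_sum / occupancy, 0.0)
    speed_ok = (occupancy > 0) & (mean_speed >= cfg.speed_threshold_cm_s)

    return BinnedSession(
        activity=mean_act.reshape(n_laps, n_bins, -1),
        occupancy=occupancy.reshape(n_laps, n_bins),
        speed_ok=speed_ok.reshape(n_laps, n_bins),
        frame_bin=frame_bin,
        frame_lap0=frame_lap0,
        n_bins=n_bins,
        bin_width_cm=spec.bin_width_cm,
    )


def tuning_curves(binned: BinnedSession) -> np.ndarray:
    """bins x rois mean activity across laps (masked cells excluded)."""
    valid = binned.valid()[:, :, None]
    act = np.where(valid, binned.activity, np.nan)
    with np.errstate(invalid="ignore"):
        curve = np.nanmean(act, axis=0)
    return np.nan_to_num(curve)


def oddeven_reliability(
    binned: BinnedSession, cfg: Optional[PipelineConfig] = None
) -> pd.DataFrame:
    """Pearson correlation between odd-lap and even-lap tuning curves per ROI.

    ROIs with r below the cutoff, or with an undefined correlation
    (zero-variance curve), are marked for exclusion.
    """
    cfg = cfg or PipelineConfig()
    odd = np.arange(binned.n_laps) % 2 == 0   # 1-based odd laps
    valid = binned.valid()[:, :, None]
    act = np.where(valid, binned.activity, np.nan)
    with np.errstate(invalid="ignore"):
        odd_curve = np.nan_to_num(np.nanmean(act[odd], axis=0))
        even_curve = np.nan_to_num(np.nanmean(act[~odd], axis=0))
    rows = []
    for roi in range(binned.n_rois):
        a, b = odd_curve[:, roi], even_curve[:, roi]
        if a.std() == 0 or b.std() == 0:
            r = np.nan
        else:
            r = float(np.corrcoef(a, b)[0, 1])
        rows.append(dict(roi_id=roi, oddeven_r=r, keep=bool(r >= cfg.oddeven_min_r)))
    return pd.DataFrame(rows)


def skaggs_information(tuning: np.ndarray, occupancy: np.ndarray) -> float:
    """Skaggs spatial information (bits per event).

    ``SI = sum_i p_i (lam_i / lam) log2(lam_i / lam)`` with ``p_i`` the
    occupancy fraction and ``lam`` the occupancy-weighted mean rate. Bins
    with zero rate contribute zero; SI is defined as 0 when the mean rate
    vanishes.
    """
    tuning = np.asarray(tuning, dtype=np.float64)
    occupancy = np.asarray(occupancy, dtype=np.float64)
    tot = occupancy.sum()
    if tot <= 0:
        raise ValueError("occupancy must sum to a positive value")
    p = occupancy / tot
    lbar = float(p @ tuning)
    if lbar <= 0:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        ratio = tuning / lbar
        terms = np.where(tuning > 0, p * ratio * np.log2(ratio), 0.0)
    return float(terms.sum())


def _si_matrix(rates: np.ndarray, p: np.ndarray) -> np.ndarray:
    """Row-wise Skaggs SI for a (n, bins) rate matrix."""
    lbar = rates @ p
    out = np.zeros(rates.shape[0])
    ok = lbar > 0
    if ok.any():
        with np.errstate(divide="ignore", invalid="ignore"):
            ratio = rates[ok] / lbar[ok, None]
            terms = np.where(rates[ok] > 0, p[None, :] * ratio * np.log2(ratio), 0.0)
        out[ok] = terms.sum(axis=1)
    return out


class CircularShiftNull:
    """Per-lap circular time-shift null for Skaggs information.

    Precomputes, for a set of frames (the whole session or one spatial
    region), the mapping from frame to effective bin and the weight each
    activity value contributes to its bin's rate; the rate definition is the
    across-lap mean of per-lap mean activity over unmasked cells. Shifting
    activity circularly within each lap's frame sequence then only permutes
    which (bin, weight) a value lands on, which makes the 1500-fold shuffle
    cheap for sparse gated activity.
    """

    def __init__(
        self,
        lap_frames: list[np.ndarray],
        frame_bin: np.ndarray,
        valid: np.ndarray,        # laps x bins inclusion mask
        occupancy: np.ndarray,    # laps x bins
        bins: np.ndarray,         # effective bin ids (sorted)
    ):
        self.lap_frames = [f for f in lap_frames if len(f)]
        self.n_bins = len(bins)
        bin_pos = -np.ones(frame_bin.max() + 2 if len(frame_bin) else 1, dtype=np.int64)
        bin_pos[bins] = np.arange(self.n_bins)

        n_inc = valid[:, bins].sum(axis=0).astype(np.float64)  # laps included per bin
        occ_inc = np.where(valid[:, bins], occupancy[:, bins], 0).sum(axis=0)
        tot = occ_inc.sum()
        self.p = occ_inc / tot if tot > 0 else np.full(self.n_bins, 1.0 / max(self.n_bins, 1))

        # per-frame destination bin (local id) and rate weight
        self.dest: list[np.ndarray] = []
        self.weight: list[np.ndarray] = []
        for frames, lap0 in zip(self.lap_frames, self._laps_of(lap_frames)):
            b = frame_bin[frames]
            local = bin_pos[b]
            w = np.zeros(len(frames))
            ok = local >= 0
            if ok.any():
                inc = valid[lap0, b[ok]]
                occ = occupancy[lap0, b[ok]].astype(np.float64)
                ninc = n_inc[local[ok]]
                w_ok = np.where(inc & (occ > 0) & (ninc > 0), 1.0 / (occ * ninc), 0.0)
                w[ok] = w_ok
            local = np.where(ok, local, 0)
            self.dest.append(local)
            self.weight.append(w)

    @staticmethod
    def _laps_of(lap_frames: list[np.ndarray]) -> list[int]:
        return [i for i, f in enumerate(lap_frames) if len(f)]

    def rates(self, values_per_lap: list[tuple[np.ndarray, np.ndarray]]) -> np.ndarray:
        """Observed rate vector from (offsets, values) per lap."""
        r = np.zeros(self.n_bins)
        for (off, val), dest, w in zip(values_per_lap, self.dest, self.weight):
            if len(off):
                np.add.at(r, dest[off], val * w[off])
        return r

    def split(self, activity: np.ndarray) -> list[tuple[np.ndarray, np.ndarray]]:
        """Non-zero activity of each lap as (offsets within lap run, values)."""
        out = []
        for frames in self.lap_frames:
            a = activity[frames]
            off = np.flatnonzero(a)
            out.append((off, a[off]))
        return out

    def si_observed(self, activity: np.ndarray) -> float:
        r = self.rates(self.split(activity))
        return float(_si_matrix(r[None, :], self.p)[0])

    def si_null(
        self, activity: np.ndarray, n_shuffles: int, rng: np.random.Generator
    ) -> np.ndarray:
        parts = self.split(activity)
        rates = np.zeros((n_shuffles, self.n_bins))
        flat = rates.ravel()
        for (off, val), frames, dest, w in zip(
            parts, self.lap_frames, self.dest, self.weight
        ):
            if len(off) == 0:
                continue
            L = len(frames)
            shifts = rng.integers(0, L, size=n_shuffles)
            newoff = (off[None, :] + shifts[:, None]) % L           # shuffles x nnz
            d = dest[newoff]
            contrib = val[None, :] * w[newoff]
            idx = (np.arange(n_shuffles)[:, None] * self.n_bins + d).ravel()
            np.add.at(flat, idx, contrib.ravel())
        return _si_matrix(rates, self.p)


def _session_null(binned: BinnedSession) -> CircularShiftNull:
    n_frames = len(binned.frame_bin)
    lap_frames = []
    for lap0 in range(binned.n_laps):
        lap_frames.append(np.flatnonzero(binned.frame_lap0 == lap0))
    return CircularShiftNull(
        lap_frames, binned.frame_bin, binned.valid(), binned.occupancy,
        np.arange(binned.n_bins),
    )


def assess_spatial_significance(
    binned: BinnedSession,
    frame_activity: np.ndarray,
    roi: int,
    *,
    cfg: Optional[PipelineConfig] = None,
    seed: int = 0,
    null: Optional[CircularShiftNull] = None,
) -> tuple[bool, float, np.ndarray]:
    """Shuffle test of one ROI's Skaggs information.

    Each of ``cfg.n_shuffles`` iterations circularly shifts every lap's
    activity in time by an independent uniform amount, re-bins, and
    recomputes SI; the ROI is significant when the observed SI exceeds the
    ``cfg.si_percentile`` percentile of this null.

    Returns ``(significant, si_observed, null_distribution)``.
    """
    cfg = cfg or PipelineConfig()
    if cfg.n_shuffles < 1:
        raise ValueError("n_shuffles must be >= 1")
    engine = null if null is not None else _session_null(binned)
    act = np.asarray(frame_activity, dtype=np.float64)
    act = act[:, roi] if act.ndim == 2 else act
    si_obs = engine.si_observed(act)
    rng = np.random.default_rng(seed)
    null_si = engine.si_null(act, cfg.n_shuffles, rng)
    significant = si_obs > np.percentile(null_si, cfg.si_percentile)
    return bool(significant), si_obs, null_si


@dataclass
class PlaceField:
    """A spatially demarcated place field (bins 0-based, bounds inclusive)."""

    roi_id: int
    bounds: tuple[int, int]
    extended_bounds: tuple[int, int]
    width_cm: float
    peak_bin: int
    peak_height: float
    local_significant: bool
    active_lap_fraction: float

    @property
    def width_bins(self) -> int:
        return self.bounds[1] - self.bounds[0] + 1


def _merge_candidates(curve: np.ndarray, cands: list[dict]) -> list[dict]:
    """Merge adjacent peaks with overlapping footprints or a shallow valley.

    Left-to-right pairwise scan, repeated until stable (idempotent on its
    own output).
    """
    cands = sorted(cands, key=lambda c: c["left"])
    changed = True
    while changed:
        changed = False
        out: list[dict] = []
        for c in cands:
            if out:
                prev = out[-1]
                overlap = c["left"] <= prev["right"]
                p1, p2 = sorted((prev["peak"], c["peak"]))
                valley = curve[p1 : p2 + 1].min() if p2 > p1 else curve[p1]
                larger = max(curve[prev["peak"]], curve[c["peak"]])
                if overlap or valley > 0.5 * larger:
                    big = prev if curve[prev["peak"]] >= curve[c["peak"]] else c
                    out[-1] = dict(
                        peak=big["peak"],
                        left=min(prev["left"], c["left"]),
                        right=max(prev["right"], c["right"]),
                    )
                    changed = True
                    continue
            out.append(dict(c))
        cands = out
    return cands


def footprint_candidates(
    curve: np.ndarray, cfg: Optional[PipelineConfig] = None
) -> list[dict]:
    """Merged peak footprints of a tuning curve (before significance tests).

    Peaks of height >= 6 a.u./frame; footprint = width at relative height
    0.93 of the prominence, edges taken as the enclosing whole bins.
    Returns dicts with keys ``peak``, ``left``, ``right`` (0-based bins,
    inclusive).
    """
    cfg = cfg or PipelineConfig()
    curve = np.asarray(curve, dtype=np.float64)
    if len(curve) < 3:
        raise ValueError("tuning curve must span at least 3 bins")
    peaks, _ = find_peaks(curve, height=cfg.peak_height)
    if len(peaks) == 0:
        return []
    prom = peak_prominences(curve, peaks)
    _, _, left_ips, right_ips = peak_widths(
        curve, peaks, rel_height=cfg.peak_rel_height, prominence_data=prom
    )
    n_bins = len(curve)
    cands = [
        dict(
            peak=int(p),
            left=max(int(np.floor(l)), 0),
            right=min(int(np.ceil(r)), n_bins - 1),
        )
        for p, l, r in zip(peaks, left_ips, right_ips)
    ]
    return _merge_candidates(curve, cands)


def demarcate_place_fields(
    curve: np.ndarray,
    binned: BinnedSession,
    frame_activity: np.ndarray,
    roi: int,
    *,
    cfg: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> list[PlaceField]:
    """Demarcate significant place fields on one ROI's tuning curve.

    Peaks (height >= 6 a.u./frame) are found with their footprints at
    relative height 0.93 of the prominence; adjacent peaks are merged when
    footprints overlap or the valley between them stays above half the
    larger peak. Each merged footprint, extended by half its width on both
    sides, is tested with a local circular-shift Skaggs null (95th
    percentile); retained fields must additionally show at least one gated
    event inside their bounds on >= 30% of laps.
    """
    cfg = cfg or PipelineConfig()
    curve = np.asarray(curve, dtype=np.float64)
    cands = footprint_candidates(curve, cfg)
    if not cands:
        return []
    n_bins = len(curve)

    act = np.asarray(frame_activity, dtype=np.float64)
    act = act[:, roi] if act.ndim == 2 else act
    valid = binned.valid()
    rng = np.random.default_rng(seed)

    fields: list[PlaceField] = []
    for c in cands:
        l, r = c["left"], c["right"]
        half = int(np.ceil((r - l + 1) / 2))
        el, er = max(l - half, 0), min(r + half, n_bins - 1)
        region = np.arange(el, er + 1)

        # local null: circular shifts within each lap's traversal of the region
        lap_frames = []
        for lap0 in range(binned.n_laps):
            fr = np.flatnonzero(
                (binned.frame_lap0 == lap0)
                & (binned.frame_bin >= el)
                & (binned.frame_bin <= er)
            )
            lap_frames.append(fr)
        engine = CircularShiftNull(
            lap_frames, binned.frame_bin, valid, binned.occupancy, region
        )
        si_obs = engine.si_observed(act)
        null = engine.si_null(act, cfg.n_shuffles, rng)
        local_sig = si_obs > np.percentile(null, cfg.local_si_percentile)

        in_bounds = (binned.frame_bin >= l) & (binned.frame_bin <= r) & (act > 0)
        active_laps = np.unique(binned.frame_lap0[in_bounds])
        frac = len(active_laps) / binned.n_laps

        if local_sig and frac >= cfg.min_active_lap_fraction:
            fields.append(
                PlaceField(
                    roi_id=roi,
                    bounds=(l, r),
                    extended_bounds=(el, er),
                    width_cm=(r - l + 1) * binned.bin_width_cm,
                    peak_bin=c["peak"],
                    peak_height=float(curve[c["peak"]]),
                    local_significant=bool(local_sig),
                    active_lap_fraction=float(frac),
                )
            )
    return fields
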