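"""Temporal demarcation and categorization of place-field formation events.

A newly formed place field (PFF) is localized in time on a thresholded
lap x bin activity matrix, filtered for lifetime and activity consistency,
and classified by three features of its lap-by-lap dynamics:

* **gain** - the formation-lap peak activity exceeds the mean peak of the
  next three active laps (signature of a large plateau-driven burst);
* **backward shift** - the mean smoothed centre of mass (COM) of the first
  three post-formation active laps lies behind the formation location;
* **drift** - a continuous backward COM trend (significant negative Spearman
  correlation from the fourth post-formation active lap whose regression,
  extrapolated back to the first post-formation lap, overshoots the
  formation location), which disqualifies the shift as a discrete jump.

``gain AND shift AND not drift`` -> BTSP-like; ``no gain AND no shift`` ->
non-BTSP-like; every other combination is excluded with a named reason.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.signal import find_peaks
from scipy.stats import spearmanr

from .config import PipelineConfig
from .tuning import BinnedSession, PlaceField

__all__ = [
    "PFActivityMatrix",
    "build_pf_activity_matrix",
    "find_formation_and_end",
    "apply_pf_filters",
    "classify_pff",
    "PFFEvent",
    "CATEGORIES",
    "misclassification_bootstrap",
    "sample_null_segments",
    "SolitaryEvent",
    "detect_solitary_events",
    "spike_fluorescence_concordance",
]

CATEGORIES = (
    "BTSP",
    "NON_BTSP",
    "EXCLUDED_GAIN_NO_SHIFT",
    "EXCLUDED_NOSHIFT_ONLY_PARTIAL",
    "EXCLUDED_DRIFT",
    "EXCLUDED_EARLY",
    "EXCLUDED_SHORT",
    "EXCLUDED_INCONSISTENT",
)


@dataclass
class PFActivityMatrix:
    """laps x bins mean activity inside a place field's extended bounds.

    Built from frame-level inferred activity floored at 64 a.u., with the
    spatial bounds extended 5 bins to the right (clipped at the corridor
    end) and *no* running-speed filtering, so that forward-located formation
    bursts are visible.
    """

    matrix: np.ndarray          # laps x bins (a.u./frame)
    bins: tuple[int, int]       # inclusive global bin interval
    bin_width_cm: float
    roi_id: int

    @property
    def n_laps(self) -> int:
        return self.matrix.shape[0]

    def lap_active(self) -> np.ndarray:
        return (self.matrix > 0).any(axis=1)

    def bin_centers_cm(self) -> np.ndarray:
        return (np.arange(self.bins[0], self.bins[1] + 1) + 0.5) * self.bin_width_cm


def build_pf_activity_matrix(
    binned: BinnedSession,
    frame_activity: np.ndarray,
    place_field: PlaceField,
    cfg: Optional[PipelineConfig] = None,
) -> PFActivityMatrix:
    """Threshold, extend, and bin one ROI's activity around a place field."""
    cfg = cfg or PipelineConfig()
    act = np.asarray(frame_activity, dtype=np.float64).copy()
    act[act < cfg.activity_floor_au] = 0.0
    l, r = place_field.bounds
    r_ext = min(r + cfg.pf_right_extension_bins, binned.n_bins - 1)
    width = r_ext - l + 1

    sel = (binned.frame_bin >= l) & (binned.frame_bin <= r_ext)
    idx = binned.frame_lap0[sel] * width + (binned.frame_bin[sel] - l)
    ncells = binned.n_laps * width
    occ = np.bincount(idx, minlength=ncells).astype(np.float64)
    sums = np.bincount(idx, weights=act[sel], minlength=ncells)
    with np.errstate(invalid="ignore", divide="ignore"):
        mat = np.where(occ > 0, sums / occ, 0.0).reshape(binned.n_laps, width)
    return PFActivityMatrix(
        matrix=mat, bins=(l, r_ext), bin_width_cm=binned.bin_width_cm,
        roi_id=place_field.roi_id,
    )


def find_formation_and_end(
    pfmat: PFActivityMatrix,
    cfg: Optional[PipelineConfig] = None,
    min_prior_laps: Optional[int] = None,
    search_from_lap: int = 1,
) -> tuple[Optional[int], int]:
    """Locate the formation lap and end lap of a candidate PFF (1-based).

    The formation lap is the earliest active lap after the first
    ``min_prior_laps`` laps (and not before ``search_from_lap``) for which
    at most 10% of all previous laps show a mean activity above 1% of the
    candidate lap's mean. The field ends at the last active lap before a
    run of five silent laps, or at the final lap of the session.
    ``search_from_lap`` lets the caller resume the scan past a candidate
    that failed the lifetime/consistency filters.
    """
    cfg = cfg or PipelineConfig()
    if min_prior_laps is None:
        min_prior_laps = cfg.min_prior_laps
    mat = pfmat.matrix
    if mat.size == 0:
        raise ValueError("empty PF activity matrix")
    n_laps = mat.shape[0]
    lap_mean = mat.mean(axis=1)
    active = pfmat.lap_active()

    formation = None
    first0 = max(min_prior_laps, search_from_lap - 1)
    for f0 in range(first0, n_laps):  # candidate lap f0+1 (1-based)
        if not active[f0]:
            continue
        if f0 == 0:
            formation = 1
            break
        n_exceed = int(
            (lap_mean[:f0] > cfg.presilence_activity_fraction * lap_mean[f0]).sum()
        )
        if n_exceed <= cfg.presilence_lap_fraction * f0:
            formation = f0 + 1
            break
    if formation is None:
        return None, n_laps

    end = n_laps
    silent = 0
    for l0 in range(formation, n_laps):
        if active[l0]:
            silent = 0
        else:
            silent += 1
            if silent >= cfg.termination_silent_laps:
                end = l0 + 1 - cfg.termination_silent_laps  # lap before the run
                break
    return formation, end


def apply_pf_filters(
    pfmat: PFActivityMatrix,
    formation_lap: int,
    end_lap: int,
    cfg: Optional[PipelineConfig] = None,
) -> tuple[bool, Optional[str]]:
    """Lifetime and activity-consistency exclusions.

    Keep iff lifetime ``end - formation + 1 >= 9`` laps and at most 8 laps
    within the lifetime have a maximum activity below 10% of the peak
    across laps.
    """
    cfg = cfg or PipelineConfig()
    lifetime = end_lap - formation_lap + 1
    if lifetime < cfg.min_lifetime_laps:
        return False, "EXCLUDED_SHORT"
    span = pfmat.matrix[formation_lap - 1 : end_lap]
    lap_max = span.max(axis=1)
    peak = lap_max.max()
    if peak <= 0:
        return False, "EXCLUDED_INCONSISTENT"
    n_silent = int((lap_max < cfg.silent_lap_fraction * peak).sum())
    if n_silent > cfg.max_silent_laps:
        return False, "EXCLUDED_INCONSISTENT"
    return True, None


@dataclass
class PFFEvent:
    """A newly formed place field with its classification."""

    roi_id: int
    place_field: PlaceField
    formation_lap: int
    end_lap: int
    gain: bool
    backward_shift: bool
    drift: bool
    category: str
    formation_location_cm: float = np.nan
    formation_amplitude: float = np.nan
    formation_speed_cm_s: float = np.nan
    com_laps: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    com_raw_cm: np.ndarray = field(default_factory=lambda: np.empty(0))
    com_smoothed_cm: np.ndarray = field(default_factory=lambda: np.empty(0))


def _smooth_com(series: np.ndarray, kernel: int) -> np.ndarray:
    return (
        pd.Series(series)
        .rolling(kernel, center=True, min_periods=1)
        .mean()
        .to_numpy()
    )


def classify_pff(
    pfmat: PFActivityMatrix,
    formation_lap: int,
    end_lap: Optional[int] = None,
    cfg: Optional[PipelineConfig] = None,
) -> PFFEvent:
    """Classify one PFF event from its activity matrix.

    Requires at least three active laps after the formation lap; otherwise
    the event is flagged ``EXCLUDED_INCONSISTENT`` (not classifiable).
    """
    cfg = cfg or PipelineConfig()
    mat = pfmat.matrix
    if end_lap is None:
        end_lap = mat.shape[0]
    active = pfmat.lap_active()
    active_laps = [l for l in range(formation_lap, end_lap + 1) if active[l - 1]]
    if not active_laps or active_laps[0] != formation_lap:
        raise ValueError("formation lap must be active")

    centers = pfmat.bin_centers_cm()
    com_raw = np.array(
        [
            float((mat[l - 1] * centers).sum() / mat[l - 1].sum())
            for l in active_laps
        ]
    )
    com_smooth = _smooth_com(com_raw, cfg.com_smooth_kernel)
    formation_location = float(com_raw[0])
    peaks = np.array([mat[l - 1].max() for l in active_laps])

    def make(gain, shift, drift, category):
        return PFFEvent(
            roi_id=pfmat.roi_id,
            place_field=None,  # attached by the pipeline
            formation_lap=formation_lap,
            end_lap=end_lap,
            gain=gain,
            backward_shift=shift,
            drift=drift,
            category=category,
            formation_location_cm=formation_location,
            formation_amplitude=float(peaks[0]),
            com_laps=np.array(active_laps),
            com_raw_cm=com_raw,
            com_smoothed_cm=com_smooth,
        )

    if len(active_laps) < 4:  # formation + three active laps
        return make(False, False, False, "EXCLUDED_INCONSISTENT")

    # strict inequalities, guarded against float rounding (e.g. a smoothed
    # COM of an exactly constant series differing from it by one ULP)
    def greater(a, b):
        return bool(a - b > 1e-9 * max(1.0, abs(a), abs(b)))

    gain = greater(float(peaks[0]), float(peaks[1:4].mean()))
    shift = greater(formation_location, float(com_smooth[1:4].mean()))

    drift = False
    tail = com_smooth[4:]
    if len(tail) >= 3 and np.ptp(tail) > 0:
        ordinals = np.arange(4, 4 + len(tail), dtype=np.float64)
        slope, intercept = np.polyfit(ordinals, tail, 1)
        extrapolated = intercept + slope * 1.0  # first post-formation active lap
        rho, p = spearmanr(tail, ordinals)
        if (
            greater(extrapolated, formation_location)
            and np.isfinite(rho)
            and rho < 0
            and np.isfinite(p)
            and p < cfg.drift_p_threshold
        ):
            drift = True

    if gain and shift and not drift:
        category = "BTSP"
    elif gain and shift and drift:
        category = "EXCLUDED_DRIFT"
    elif not gain and not shift:
        category = "NON_BTSP"
    elif gain and not shift:
        category = "EXCLUDED_GAIN_NO_SHIFT"
    else:  # not gain, shift
        category = "EXCLUDED_NOSHIFT_ONLY_PARTIAL"
    return make(gain, shift, drift, category)


# ---------------------------------------------------------------------------
# misclassification bootstrap


def sample_null_segments(
    binned_thresh: np.ndarray,     # laps x bins x rois, floored activity
    pf_bounds: dict[int, list[tuple[int, int]]],
    n_laps_test: int,
    n_bins_test: int,
    n_null: int,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Null (mean activity, active-lap fraction) from outside-PF segments.

    Segments of ``n_laps_test x n_bins_test`` are sampled uniformly over
    (ROI, lap window, bin window) placements whose bin window does not
    intersect any of that ROI's place fields.
    """
    n_laps, n_bins, n_rois = binned_thresh.shape
    if n_laps_test > n_laps or n_bins_test > n_bins:
        raise ValueError("test segment larger than the session")
    placements: list[tuple[int, int]] = []  # (roi, bin_start)
    for roi in range(n_rois):
        bounds = pf_bounds.get(roi, [])
        for b in range(n_bins - n_bins_test + 1):
            if all(b + n_bins_test - 1 < l or b > r for (l, r) in bounds):
                placements.append((roi, b))
    if not placements:
        raise ValueError(
            f"no outside-PF placements available for a {n_laps_test}x{n_bins_test} "
            f"segment across {n_rois} ROIs"
        )
    pick = rng.integers(0, len(placements), size=n_null)
    lap0 = rng.integers(0, n_laps - n_laps_test + 1, size=n_null)
    means = np.empty(n_null)
    fracs = np.empty(n_null)
    for i, (k, l0) in enumerate(zip(pick, lap0)):
        roi, b = placements[k]
        seg = binned_thresh[l0 : l0 + n_laps_test, b : b + n_bins_test, roi]
        means[i] = seg.mean()
        fracs[i] = (seg > 0).any(axis=1).mean()
    return means, fracs


def misclassification_bootstrap(
    event: PFFEvent,
    pfmat: PFActivityMatrix,
    binned_thresh: np.ndarray,
    pf_bounds: dict[int, list[tuple[int, int]]],
    cfg: Optional[PipelineConfig] = None,
    seed: int = 0,
) -> tuple[float, bool]:
    """Probability that a non-BTSP PFF hides a later BTSP-like formation.

    Laps are masked sequentially from the event's formation lap until
    re-running formation detection and classification on the masked matrix
    yields a BTSP-like event, or the field ends. Without a hidden BTSP
    signature the probability is zero. Otherwise the activity between the
    non-BTSP start and the hidden BTSP formation lap (the *test area*) is
    compared against null segments sampled outside all place fields: the
    probability is the fraction of null samples at least as large on both
    the mean activity and the active-lap fraction, and the event is deemed
    unlikely-misclassified when that fraction is below 5%.
    """
    cfg = cfg or PipelineConfig()
    if event.category != "NON_BTSP":
        raise ValueError("misclassification bootstrap applies to NON_BTSP events")
    f, end = event.formation_lap, event.end_lap
    hidden_formation = None
    for k in range(f, end + 1):
        masked = PFActivityMatrix(
            matrix=pfmat.matrix.copy(), bins=pfmat.bins,
            bin_width_cm=pfmat.bin_width_cm, roi_id=pfmat.roi_id,
        )
        masked.matrix[f - 1 : k] = 0.0
        mf, mend = find_formation_and_end(masked, cfg)
        if mf is None:
            continue
        keep, _ = apply_pf_filters(masked, mf, mend, cfg)
        if not keep:
            continue
        cand = classify_pff(masked, mf, mend, cfg)
        if cand.category == "BTSP":
            hidden_formation = mf
            break
    if hidden_formation is None:
        return 0.0, True

    n_laps_test = hidden_formation - f
    n_bins_test = pfmat.matrix.shape[1]
    seg = pfmat.matrix[f - 1 : hidden_formation - 1]
    test_mean = float(seg.mean())
    test_frac = float((seg > 0).any(axis=1).mean())
    rng = np.random.default_rng(seed)
    means, fracs = sample_null_segments(
        binned_thresh, pf_bounds, n_laps_test, n_bins_test, cfg.bootstrap_n_null, rng
    )
    prob = float(np.mean((means >= test_mean) & (fracs >= test_frac)))
    return prob, bool(prob < cfg.bootstrap_alpha)


# ---------------------------------------------------------------------------
# solitary transients


@dataclass
class SolitaryEvent:
    """A large, isolated calcium transient outside any place field."""

    roi_id: int
    lap: int
    bin: int
    frame: int
    amplitude: float            # dF/F at the peak
    reference: float            # formation-lap max dF/F used as threshold


def detect_solitary_events(
    dff: np.ndarray,
    binned: BinnedSession,
    events: Sequence[PFFEvent],
    place_fields: dict[int, list[PlaceField]],
    cfg: Optional[PipelineConfig] = None,
) -> list[SolitaryEvent]:
    """Detect solitary transients in ROIs that own a BTSP-like PFF.

    For each such ROI the reference amplitude is the maximum dF/F reached
    while traversing the field (extended 5 bins rightward) on the formation
    lap. dF/F peaks at least that large (``find_peaks``: prominence 1,
    minimum separation 20 samples) are kept when they fall outside all of
    the ROI's place fields and their spatial context (previous and following
    5 laps, 11 bins centred on the peak) stays below the ROI's session
    median + 2 SD of dF/F. Only the largest qualifying peak per ROI is
    reported (ties broken by earliest lap).
    """
    cfg = cfg or PipelineConfig()
    dff = np.atleast_2d(np.asarray(dff, dtype=np.float64))
    out: list[SolitaryEvent] = []
    by_roi: dict[int, list[PFFEvent]] = {}
    for ev in events:
        if ev.category == "BTSP":
            by_roi.setdefault(ev.roi_id, []).append(ev)

    half_bins = cfg.solitary_context_bins // 2
    for roi, roi_events in sorted(by_roi.items()):
        trace = dff[:, roi]
        refs = []
        for ev in roi_events:
            l, r = ev.place_field.bounds
            r_ext = min(r + cfg.pf_right_extension_bins, binned.n_bins - 1)
            sel = (
                (binned.frame_lap0 == ev.formation_lap - 1)
                & (binned.frame_bin >= l)
                & (binned.frame_bin <= r_ext)
            )
            if sel.any():
                refs.append(float(trace[sel].max()))
        if not refs:
            continue
        ref = min(refs)

        peaks, _ = find_peaks(
            trace, prominence=cfg.solitary_prominence, distance=cfg.solitary_distance
        )
        peaks = peaks[trace[peaks] >= ref]
        ctx_thresh = float(np.median(trace) + cfg.solitary_context_sd * trace.std())
        bounds = [pf.bounds for pf in place_fields.get(roi, [])]

        best: Optional[SolitaryEvent] = None
        for pk in peaks:
            b = int(binned.frame_bin[pk])
            if any(l <= b <= r for (l, r) in bounds):
                continue
            lap0 = int(binned.frame_lap0[pk])
            ctx = (
                (binned.frame_lap0 >= lap0 - cfg.solitary_context_laps)
                & (binned.frame_lap0 <= lap0 + cfg.solitary_context_laps)
                & (binned.frame_lap0 != lap0)
                & (binned.frame_bin >= b - half_bins)
                & (binned.frame_bin <= b + half_bins)
            )
            if ctx.any() and trace[ctx].max() > ctx_thresh:
                continue
            cand = SolitaryEvent(
                roi_id=roi, lap=lap0 + 1, bin=b, frame=int(pk),
                amplitude=float(trace[pk]), reference=ref,
            )
            if (
                best is None
                or cand.amplitude > best.amplitude
                or (cand.amplitude == best.amplitude and cand.lap < best.lap)
            ):
                best = cand
        if best is not None:
            out.append(best)
    return out


# ---------------------------------------------------------------------------
# inferred-spike vs fluorescence concordance


def spike_fluorescence_concordance(
    dff_roi: np.ndarray,
    binned: BinnedSession,
    roi: int,
    fields: Sequence[PlaceField],
) -> tuple[float, np.ndarray]:
    """Correlate per-lap dF/F maxima with inferred-activity maxima in PFs.

    All of the ROI's place-field windows are concatenated along the lap
    dimension; for every (field, lap) row the maximum dF/F during the
    traversal and the maximum bin-wise mean inferred activity are extracted
    and Pearson-correlated. The null applies every possible lap-wise
    circular permutation to the activity maxima.
    """
    if not fields:
        raise ValueError("ROI has no place fields")
    x, y = [], []
    for pf in fields:
        l, r = pf.bounds
        for lap0 in range(binned.n_laps):
            sel = (
                (binned.frame_lap0 == lap0)
                & (binned.frame_bin >= l)
                & (binned.frame_bin <= r)
            )
            x.append(float(dff_roi[sel].max()) if sel.any() else np.nan)
            y.append(float(binned.activity[lap0, l : r + 1, roi].max()))
    x = np.asarray(x)
    y = np.asarray(y)
    ok = np.isfinite(x) & np.isfinite(y)
    x, y = x[ok], y[ok]
    if len(x) < 3 or x.std() == 0 or y.std() == 0:
        return np.nan, np.empty(0)
    r = float(np.corrcoef(x, y)[0, 1])
    null = np.array(
        [np.corrcoef(x, np.roll(y, s))[0, 1] for s in range(len(y))]
    )
    return r, null
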