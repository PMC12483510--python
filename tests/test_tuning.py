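"""Spatial binning, Skaggs information, shuffle nulls, PF demarcation."""

import numpy as np
import pytest

from pffpipe.config import CorridorSpec, PipelineConfig
from pffpipe.session import BehaviorTrace
from pffpipe.synth import simulate_behavior, simulate_untuned_activity
from pffpipe.tuning import (
    assess_spatial_significance,
    bin_session,
    demarcate_place_fields,
    footprint_candidates,
    oddeven_reliability,
    skaggs_information,
    tuning_curves,
    _merge_candidates,
    _session_null,
)


def two_lap_behavior(speeds=(40.0, 40.0), frames_per_lap=400):
    """Hand-built behavior: uniform sweep of the corridor on each lap."""
    spec = CorridorSpec()
    pos, spd, lap = [], [], []
    for i, v in enumerate(speeds):
        p = np.linspace(0, spec.length_cm, frames_per_lap, endpoint=False)
        pos.append(p)
        spd.append(np.full(frames_per_lap, v))
        lap.append(np.full(frames_per_lap, i + 1))
    n = frames_per_lap * len(speeds)
    return spec, BehaviorTrace(
        time_s=np.arange(n) / 31.0,
        position_cm=np.concatenate(pos),
        speed_cm_s=np.concatenate(spd),
        lap_index=np.concatenate(lap),
    )


class TestBinSession:
    def test_196_bins_for_default_geometry(self):
        assert CorridorSpec().n_bins == 196

    def test_slow_lap_fully_masked(self):
        spec, beh = two_lap_behavior(speeds=(40.0, 3.0))
        binned = bin_session(beh, np.zeros((beh.n_frames, 1)), spec)
        assert binned.speed_ok[0][binned.occupancy[0] > 0].all()
        assert not binned.speed_ok[1].any()  # 3 cm/s < 4 cm/s threshold

    def test_mean_activity_matches_frame_accumulation_oracle(self, rng):
        spec = CorridorSpec()
        beh = simulate_behavior(spec, 3, seed=2)
        act = np.where(rng.random((beh.n_frames, 2)) < 0.1,
                       rng.exponential(100, (beh.n_frames, 2)), 0)
        binned = bin_session(beh, act, spec)
        bins = spec.bin_of(beh.position_cm)
        for roi in range(2):
            oracle = np.zeros((3, spec.n_bins))
            count = np.zeros((3, spec.n_bins))
            for f in range(beh.n_frames):
                l, b = beh.lap_index[f] - 1, bins[f]
                oracle[l, b] += act[f, roi]
                count[l, b] += 1
            oracle = np.where(count > 0, oracle / np.maximum(count, 1), 0)
            assert np.allclose(binned.activity[:, :, roi], oracle, rtol=1e-10)

    def test_frame_mismatch_rejected(self):
        spec, beh = two_lap_behavior()
        with pytest.raises(ValueError):
            bin_session(beh, np.zeros((10, 1)), spec)


class TestOddEven:
    def test_identical_laps_r_one_kept(self):
        spec, beh = two_lap_behavior(speeds=(40.0,) * 4)
        act = np.zeros((beh.n_frames, 1))
        bins = spec.bin_of(beh.position_cm)
        act[(bins >= 50) & (bins <= 55), 0] = 100.0
        binned = bin_session(beh, act, spec)
        oe = oddeven_reliability(binned)
        assert oe.oddeven_r.iloc[0] == pytest.approx(1.0)
        assert oe.keep.iloc[0]

    def test_silent_roi_undefined_excluded(self):
        spec, beh = two_lap_behavior(speeds=(40.0,) * 4)
        binned = bin_session(beh, np.zeros((beh.n_frames, 1)), spec)
        oe = oddeven_reliability(binned)
        assert np.isnan(oe.oddeven_r.iloc[0])
        assert not oe.keep.iloc[0]

    def test_r_matches_direct_correlation_oracle(self, rng):
        spec, beh = two_lap_behavior(speeds=(40.0,) * 6)
        act = rng.exponential(50, (beh.n_frames, 3))
        binned = bin_session(beh, act, spec)
        oe = oddeven_reliability(binned)
        valid = binned.valid()[:, :, None]
        masked = np.where(valid, binned.activity, np.nan)
        for roi in range(3):
            odd = np.nan_to_num(np.nanmean(masked[0::2, :, roi], axis=0))
            even = np.nan_to_num(np.nanmean(masked[1::2, :, roi], axis=0))
            r = np.corrcoef(odd, even)[0, 1]
            assert oe.oddeven_r.iloc[roi] == pytest.approx(r, rel=1e-10)
            assert oe.keep.iloc[roi] == (r >= 0.25)


class TestSkaggs:
    def test_uniform_rate_zero_bits(self):
        assert skaggs_information(np.full(10, 3.0), np.full(10, 7.0)) == 0.0

    def test_single_bin_of_eight_is_three_bits(self):
        tuning = np.zeros(8)
        tuning[2] = 5.0
        assert skaggs_information(tuning, np.ones(8)) == pytest.approx(3.0)

    def test_matches_term_by_term_oracle(self, rng):
        tuning = rng.exponential(2.0, 12)
        occ = rng.integers(1, 50, 12).astype(float)
        p = occ / occ.sum()
        lbar = (p * tuning).sum()
        expected = sum(
            p[i] * (tuning[i] / lbar) * np.log2(tuning[i] / lbar)
            for i in range(12)
            if tuning[i] > 0
        )
        assert skaggs_information(tuning, occ) == pytest.approx(expected, rel=1e-12)

    def test_scale_invariance(self, rng):
        tuning = rng.exponential(1.0, 20)
        occ = rng.integers(1, 9, 20).astype(float)
        a = skaggs_information(tuning, occ)
        b = skaggs_information(10.0 * tuning, occ)
        assert a == pytest.approx(b, rel=1e-12)

    def test_zero_rate_defined_as_zero(self):
        assert skaggs_information(np.zeros(5), np.ones(5)) == 0.0

    def test_bad_occupancy_rejected(self):
        with pytest.raises(ValueError):
            skaggs_information(np.ones(3), np.zeros(3))


class TestSpatialSignificance:
    def test_time_constant_activity_never_significant(self):
        # constant activity is invariant under circular shifts: the null
        # collapses onto the observed SI, which also conserves each lap's mass
        spec, beh = two_lap_behavior(speeds=(40.0,) * 4)
        act = np.full(beh.n_frames, 5.0)
        binned = bin_session(beh, act[:, None], spec)
        cfg = PipelineConfig(n_shuffles=100)
        sig, si, null = assess_spatial_significance(binned, act, 0, cfg=cfg, seed=0)
        assert not sig
        assert np.allclose(null, si, atol=1e-10)

    def test_tuned_cell_significant(self, small_session):
        s = small_session
        ev = next(e for e in s.truth.events if e.kind == "BTSP")
        binned = bin_session(s.behavior, s.deconvolved, s.corridor)
        sig, si, null = assess_spatial_significance(
            binned, s.deconvolved[:, ev.roi_id], 0, seed=1,
            null=_session_null(binned),
        )
        assert sig and si > np.median(null)

    def test_untuned_cells_mostly_not_significant(self):
        spec = CorridorSpec()
        beh = simulate_behavior(spec, 15, seed=3)
        act = simulate_untuned_activity(beh, 10, seed=4)
        binned = bin_session(beh, act, spec)
        engine = _session_null(binned)
        cfg = PipelineConfig(n_shuffles=300)
        flags = [
            assess_spatial_significance(binned, act, r, cfg=cfg, seed=10 + r,
                                        null=engine)[0]
            for r in range(10)
        ]
        assert sum(flags) <= 2


def width_at_level_oracle(curve, peak, level):
    """Independent crossing search for the footprint at an evaluation level."""
    left = peak
    while left > 0 and curve[left - 1] > level:
        left -= 1
    lf = float(left)
    if left > 0:  # interpolate between the samples straddling the level
        lf = left - (curve[left] - level) / (curve[left] - curve[left - 1])
    right = peak
    n = len(curve)
    while right < n - 1 and curve[right + 1] > level:
        right += 1
    rf = float(right)
    if right < n - 1:
        rf = right + (curve[right] - level) / (curve[right] - curve[right + 1])
    return lf, rf


class TestDemarcation:
    def test_flat_curve_no_fields(self):
        assert footprint_candidates(np.zeros(196)) == []

    def test_short_curve_rejected(self):
        with pytest.raises(ValueError):
            footprint_candidates(np.array([1.0, 2.0]))

    def test_gaussian_bump_bounds_match_level_crossing_oracle(self):
        b = np.arange(196, dtype=float)
        curve = 20.0 * np.exp(-((b - 100.0) ** 2) / (2 * 5.0**2))
        cands = footprint_candidates(curve)
        assert len(cands) == 1
        c = cands[0]
        assert c["peak"] == 100
        level = 20.0 - 0.93 * 20.0  # full prominence for an isolated peak
        lf, rf = width_at_level_oracle(curve, 100, level)
        assert c["left"] == int(np.floor(lf))
        assert c["right"] == int(np.ceil(rf))

    def test_overlapping_footprints_merge_to_one(self):
        b = np.arange(196, dtype=float)
        curve = 20.0 * np.exp(-((b - 95.0) ** 2) / 50.0) + 18.0 * np.exp(
            -((b - 103.0) ** 2) / 50.0
        )
        cands = footprint_candidates(curve)
        assert len(cands) == 1

    def test_merge_idempotent(self, rng):
        b = np.arange(196, dtype=float)
        curve = np.zeros(196)
        for c, h in [(40, 15.0), (60, 25.0), (130, 10.0)]:
            curve += h * np.exp(-((b - c) ** 2) / 40.0)
        merged = footprint_candidates(curve)
        assert _merge_candidates(curve, [dict(m) for m in merged]) == merged

    def test_distant_peaks_stay_separate(self):
        b = np.arange(196, dtype=float)
        curve = 20.0 * np.exp(-((b - 40.0) ** 2) / 30.0) + 20.0 * np.exp(
            -((b - 150.0) ** 2) / 30.0
        )
        assert len(footprint_candidates(curve)) == 2

    def test_demarcate_recovers_implanted_field(self, small_session):
        s = small_session
        ev = next(e for e in s.truth.events if e.kind == "BTSP")
        binned = bin_session(s.behavior, s.deconvolved, s.corridor)
        curves = tuning_curves(binned)
        fields = demarcate_place_fields(
            curves[:, ev.roi_id], binned, s.deconvolved[:, ev.roi_id],
            ev.roi_id, seed=3,
        )
        assert len(fields) >= 1
        center_bin = int(ev.center_cm / s.corridor.bin_width_cm)
        assert any(pf.bounds[0] <= center_bin <= pf.bounds[1] for pf in fields)
        # reproducibility under a fixed seed
        again = demarcate_place_fields(
            curves[:, ev.roi_id], binned, s.deconvolved[:, ev.roi_id],
            ev.roi_id, seed=3,
        )
        assert [pf.bounds for pf in again] == [pf.bounds for pf in fields]
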