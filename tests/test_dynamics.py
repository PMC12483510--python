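"""Temporal demarcation, BTSP/non-BTSP categorization, bootstrap, solitary."""

import numpy as np
import pandas as pd
import pytest

from pffpipe.config import CorridorSpec, PipelineConfig
from pffpipe.dynamics import (
    PFActivityMatrix,
    apply_pf_filters,
    build_pf_activity_matrix,
    classify_pff,
    detect_solitary_events,
    find_formation_and_end,
    misclassification_bootstrap,
    sample_null_segments,
    spike_fluorescence_concordance,
)
from pffpipe.tuning import PlaceField, bin_session
from pffpipe.synth import simulate_behavior

BW = 4.24


def pf_matrix(matrix, left_bin=50):
    return PFActivityMatrix(
        matrix=np.asarray(matrix, dtype=float), bins=(left_bin, left_bin + matrix.shape[1] - 1),
        bin_width_cm=BW, roi_id=0,
    )


def make_matrix(n_laps, n_bins, events):
    """events: list of (lap 1-based, bin, value)."""
    m = np.zeros((n_laps, n_bins))
    for lap, b, v in events:
        m[lap - 1, b] = v
    return pf_matrix(m)


def field(roi_id=0, bounds=(50, 53)):
    return PlaceField(
        roi_id=roi_id, bounds=bounds,
        extended_bounds=(max(bounds[0] - 2, 0), bounds[1] + 2),
        width_cm=(bounds[1] - bounds[0] + 1) * BW, peak_bin=bounds[0] + 1,
        peak_height=100.0, local_significant=True, active_lap_fraction=1.0,
    )


class TestBuildPFMatrix:
    def test_threshold_boundary_63_zeroed_64_kept(self):
        spec = CorridorSpec()
        beh = simulate_behavior(spec, 2, mean_speed_cm_s=41.6, lap_speed_jitter=0,
                                frame_speed_jitter=0, slowdown_factor=1.0, seed=0)
        binned = bin_session(beh, np.zeros((beh.n_frames, 1)), spec)
        act = np.zeros(beh.n_frames)
        bins = spec.bin_of(beh.position_cm)
        lap1 = beh.lap_index == 1
        act[lap1 & (bins == 51)] = 63.0
        act[lap1 & (bins == 52)] = 64.0
        mat = build_pf_activity_matrix(binned, act, field(bounds=(50, 53)))
        assert mat.matrix[0, 1] == 0.0     # 63 a.u. falls below the floor
        assert mat.matrix[0, 2] == 64.0    # 64 a.u. is kept

    def test_extension_clipped_at_corridor_end(self):
        spec = CorridorSpec()
        beh = simulate_behavior(spec, 1, seed=0)
        binned = bin_session(beh, np.zeros((beh.n_frames, 1)), spec)
        mat = build_pf_activity_matrix(
            binned, np.zeros(beh.n_frames), field(bounds=(192, 195))
        )
        assert mat.bins == (192, 195)

    def test_matches_mask_and_floor_oracle(self, rng):
        spec = CorridorSpec()
        beh = simulate_behavior(spec, 4, seed=5)
        act = np.where(rng.random(beh.n_frames) < 0.2,
                       rng.exponential(80, beh.n_frames), 0.0)
        binned = bin_session(beh, act[:, None], spec)
        pf = field(bounds=(60, 64))
        mat = build_pf_activity_matrix(binned, act, pf)
        bins = spec.bin_of(beh.position_cm)
        floored = np.where(act >= 64.0, act, 0.0)
        oracle = np.zeros_like(mat.matrix)
        cnt = np.zeros_like(mat.matrix)
        for f in range(beh.n_frames):
            b = bins[f]
            if 60 <= b <= 69:
                oracle[beh.lap_index[f] - 1, b - 60] += floored[f]
                cnt[beh.lap_index[f] - 1, b - 60] += 1
        oracle = np.where(cnt > 0, oracle / np.maximum(cnt, 1), 0.0)
        assert mat.bins == (60, 69)
        assert np.allclose(mat.matrix, oracle, rtol=1e-10)


class TestFormationAndEnd:
    def test_silent_then_active(self):
        mat = make_matrix(40, 4, [(l, 1, 100.0) for l in range(25, 41)])
        f, end = find_formation_and_end(mat)
        assert (f, end) == (25, 40)

    def test_activity_before_lap_18_rejected_by_default(self):
        mat = make_matrix(40, 4, [(l, 1, 100.0) for l in range(15, 41)])
        f, _ = find_formation_and_end(mat)
        assert f is None  # >10% of prior laps active for every later candidate
        f2, _ = find_formation_and_end(mat, min_prior_laps=0)
        assert f2 == 15

    def test_end_at_five_silent_laps(self):
        mat = make_matrix(40, 4, [(l, 1, 100.0) for l in list(range(20, 28))])
        f, end = find_formation_and_end(mat)
        assert (f, end) == (20, 27)

    def test_matches_exhaustive_rule_oracle(self, rng):
        cfg = PipelineConfig()
        for trial in range(30):
            m = np.where(rng.random((45, 3)) < 0.15,
                         rng.exponential(120, (45, 3)), 0.0)
            mat = pf_matrix(m)
            f, end = find_formation_and_end(mat, cfg)
            # brute-force candidate scan
            lap_mean = m.mean(axis=1)
            active = (m > 0).any(axis=1)
            expect = None
            for lap in range(18, 46):
                if not active[lap - 1]:
                    continue
                prior = lap_mean[: lap - 1]
                if (prior > 0.01 * lap_mean[lap - 1]).sum() <= 0.10 * (lap - 1):
                    expect = lap
                    break
            assert f == expect
            if expect is not None:
                e = 45
                run = 0
                for lap in range(expect + 1, 46):
                    run = 0 if active[lap - 1] else run + 1
                    if run == 5:
                        e = lap - 5
                        break
                assert end == e


class TestFilters:
    def test_lifetime_8_excluded(self):
        mat = make_matrix(40, 4, [(l, 1, 100.0) for l in range(20, 28)])
        keep, reason = apply_pf_filters(mat, 20, 27)
        assert not keep and reason == "EXCLUDED_SHORT"

    def test_nine_silent_laps_excluded(self):
        events = [(l, 1, 100.0) for l in (20, 21, 22, 32)]
        mat = make_matrix(40, 4, events)
        keep, reason = apply_pf_filters(mat, 20, 32)  # 9 silent laps inside
        assert not keep and reason == "EXCLUDED_INCONSISTENT"

    def test_compliant_field_kept(self):
        mat = make_matrix(40, 4, [(l, 1, 100.0) for l in range(20, 35)])
        keep, reason = apply_pf_filters(mat, 20, 34)
        assert keep and reason is None


def com_series_matrix(formation_bin, post_bins, amps, n_bins=12, n_laps=None):
    """Matrix with formation at lap 20 and one active bin per later lap."""
    laps = 20 + len(post_bins)
    n_laps = n_laps or laps + 5
    events = [(20, formation_bin, amps[0])]
    for i, (b, a) in enumerate(zip(post_bins, amps[1:]), start=1):
        events.append((20 + i, b, a))
    m = make_matrix(n_laps, n_bins, events)
    return m


class TestClassify:
    def test_gain_example(self):
        # formation peak 100 vs next three active-lap peaks {40, 50, 60}
        m = com_series_matrix(5, [5] * 10, [100, 40, 50, 60] + [50] * 7)
        ev = classify_pff(m, 20)
        assert ev.gain

    def test_backward_shift_example(self):
        # formation COM forward of the subsequent laps' COM
        m = com_series_matrix(8, [5] * 10, [100] + [50] * 10)
        ev = classify_pff(m, 20)
        assert ev.backward_shift

    @pytest.mark.parametrize(
        "formation_bin,post_bins,amps,expected",
        [
            # gain + shift, no drift -> BTSP
            (8, [5] * 10, [100] + [40] * 10, "BTSP"),
            # no gain, no shift -> NON_BTSP
            (5, [5] * 10, [40] + [50] * 10, "NON_BTSP"),
            # gain, no shift -> excluded
            (5, [5] * 10, [100] + [40] * 10, "EXCLUDED_GAIN_NO_SHIFT"),
            # no gain, shift -> excluded
            (8, [5] * 10, [40] + [50] * 10, "EXCLUDED_NOSHIFT_ONLY_PARTIAL"),
            # gain + shift, then steady backward drift whose regression
            # back-extrapolates above the formation location -> excluded
            (12, [11, 11, 11, 10, 9, 8, 7, 6, 5, 4],
             [100] + [40] * 10, "EXCLUDED_DRIFT"),
        ],
        ids=["btsp", "non_btsp", "gain_only", "shift_only", "drift"],
    )
    def test_truth_table(self, formation_bin, post_bins, amps, expected):
        m = com_series_matrix(formation_bin, post_bins, amps, n_bins=16)
        ev = classify_pff(m, 20)
        assert ev.category == expected

    def test_drift_oracle_flags(self):
        # the drift case must show gain and shift flags too
        m = com_series_matrix(12, [11, 11, 11, 10, 9, 8, 7, 6, 5, 4],
                              [100] + [40] * 10, n_bins=16)
        ev = classify_pff(m, 20)
        assert ev.gain and ev.backward_shift and ev.drift

    def test_random_series_match_truth_table_oracle(self, rng):
        # independent re-derivation of the gain/shift/drift rules from the
        # COM and peak definitions, checked over random single-bin series
        import pandas as pd
        from scipy.stats import spearmanr as sp

        for _ in range(40):
            n_post = int(rng.integers(8, 14))
            post_bins = rng.integers(0, 14, n_post)
            f_bin = int(rng.integers(0, 14))
            amps = np.round(rng.uniform(65, 300, n_post + 1), 1)
            m = com_series_matrix(f_bin, list(post_bins), list(amps), n_bins=16)
            ev = classify_pff(m, 20)

            centers = (np.arange(50, 66) + 0.5) * BW
            com = centers[np.r_[f_bin, post_bins]]
            sm = pd.Series(com).rolling(3, center=True, min_periods=1).mean().to_numpy()
            gain = amps[0] > amps[1:4].mean() + 1e-9
            shift = sm[1:4].mean() < com[0] - 1e-9
            tail = sm[4:]
            drift = False
            if len(tail) >= 3 and np.ptp(tail) > 0:
                x = np.arange(4, 4 + len(tail), dtype=float)
                s, i = np.polyfit(x, tail, 1)
                rho, p = sp(tail, x)
                drift = bool(i + s > com[0] + 1e-9 and rho < 0 and p < 0.05)
            if gain and shift and not drift:
                expected = "BTSP"
            elif gain and shift:
                expected = "EXCLUDED_DRIFT"
            elif not gain and not shift:
                expected = "NON_BTSP"
            elif gain:
                expected = "EXCLUDED_GAIN_NO_SHIFT"
            else:
                expected = "EXCLUDED_NOSHIFT_ONLY_PARTIAL"
            assert ev.category == expected

    def test_scale_invariance(self):
        m = com_series_matrix(8, [5] * 10, [100] + [40] * 10)
        ev1 = classify_pff(m, 20)
        m2 = pf_matrix(m.matrix * 37.5)
        ev2 = classify_pff(m2, 20)
        assert (ev1.gain, ev1.backward_shift, ev1.drift, ev1.category) == (
            ev2.gain, ev2.backward_shift, ev2.drift, ev2.category)

    def test_shift_sign_correctness(self):
        fwd = com_series_matrix(8, [5] * 10, [100] + [40] * 10)
        assert classify_pff(fwd, 20).backward_shift
        # mirrored: formation behind the subsequent laps
        rev = com_series_matrix(2, [5] * 10, [100] + [40] * 10)
        assert not classify_pff(rev, 20).backward_shift

    def test_too_few_post_laps_flagged(self):
        m = com_series_matrix(5, [5, 5], [100, 40, 40])
        ev = classify_pff(m, 20)
        assert ev.category == "EXCLUDED_INCONSISTENT"

    def test_formation_must_be_active(self):
        m = make_matrix(30, 4, [(25, 1, 100.0)])
        with pytest.raises(ValueError):
            classify_pff(m, 20)


class TestBootstrap:
    def build_non_btsp(self, pre_activity=0.0):
        """Non-BTSP event whose masking reveals a BTSP-like pattern."""
        n_laps, n_bins = 60, 8
        m = np.zeros((n_laps, n_bins))
        # small early activity (the non-BTSP start), laps 20..24 at bin 4
        for lap in range(20, 25):
            m[lap - 1, 4] = 70.0 + pre_activity
        # strong BTSP-like pattern from lap 25: big forward burst, then
        # smaller backward events
        m[24, 6] = 500.0
        for lap in range(26, 56):
            m[lap - 1, 3] = 150.0
        return pf_matrix(m)

    def test_masking_reveals_hidden_btsp(self, rng):
        mat = self.build_non_btsp()
        f, end = find_formation_and_end(mat)
        assert f == 20
        ev = classify_pff(mat, f, end)
        assert ev.category == "NON_BTSP"
        binned_thresh = np.zeros((60, 196, 5))
        # silent null territory -> every null sample is dominated by the test
        prob, unlikely = misclassification_bootstrap(
            ev, mat, binned_thresh, {0: [(50, 57)]}, seed=0
        )
        assert prob == 0.0 or prob < 0.05
        assert unlikely

    def test_no_hidden_signature_probability_zero(self):
        # uniform non-BTSP activity: masking never reveals gain
        n_laps, n_bins = 60, 8
        m = np.zeros((n_laps, n_bins))
        for lap in range(20, 56):
            m[lap - 1, 4] = 100.0
        mat = pf_matrix(m)
        f, end = find_formation_and_end(mat)
        ev = classify_pff(mat, f, end)
        assert ev.category == "NON_BTSP"
        prob, unlikely = misclassification_bootstrap(
            ev, mat, np.zeros((60, 196, 3)), {}, seed=0
        )
        assert prob == 0.0 and unlikely

    def test_null_sampling_matches_brute_force_oracle(self, rng):
        binned = np.where(rng.random((30, 50, 4)) < 0.1,
                          rng.exponential(100, (30, 50, 4)), 0.0)
        pf_bounds = {0: [(10, 20)], 2: [(0, 45)]}
        n_laps_t, n_bins_t = 5, 6
        means, fracs = sample_null_segments(
            binned, pf_bounds, n_laps_t, n_bins_t, 200,
            np.random.default_rng(7),
        )
        # identical placement enumeration and rng stream, independent metric code
        placements = []
        for roi in range(4):
            for b in range(50 - n_bins_t + 1):
                if all(b + n_bins_t - 1 < l or b > r
                       for (l, r) in pf_bounds.get(roi, [])):
                    placements.append((roi, b))
        rng2 = np.random.default_rng(7)
        pick = rng2.integers(0, len(placements), size=200)
        lap0 = rng2.integers(0, 30 - n_laps_t + 1, size=200)
        for i in range(200):
            roi, b = placements[pick[i]]
            seg = binned[lap0[i] : lap0[i] + n_laps_t, b : b + n_bins_t, roi]
            total, cells, active = 0.0, 0, 0
            for lap in range(n_laps_t):
                lap_any = False
                for bb in range(n_bins_t):
                    total += seg[lap, bb]
                    cells += 1
                    lap_any = lap_any or seg[lap, bb] > 0
                active += lap_any
            assert means[i] == pytest.approx(total / cells, rel=1e-12)
            assert fracs[i] == pytest.approx(active / n_laps_t, rel=1e-12)

    def test_insufficient_outside_area_raises(self):
        binned = np.zeros((30, 50, 1))
        with pytest.raises(ValueError, match="placements"):
            sample_null_segments(binned, {0: [(0, 49)]}, 5, 6, 10,
                                 np.random.default_rng(0))


class TestSolitary:
    def test_detected_recovered_and_pf_peaks_excluded(self, small_session, small_result):
        truth_sol = [e for e in small_session.truth.events if e.kind == "SOLITARY"]
        found = small_result.solitary_table
        assert len(found) == len(truth_sol)
        spec = small_session.corridor
        for ev in truth_sol:
            row = found[found.roi_id == ev.roi_id]
            assert len(row) == 1
            assert row.lap.iloc[0] == ev.formation_lap
            # detected peak lies near the implanted bin, outside the PF
            assert abs(row.bin.iloc[0] - int(ev.center_cm / spec.bin_width_cm)) <= 6
        # no detection inside any demarcated field of its ROI
        pf = small_result.place_field_table
        for _, row in found.iterrows():
            own = pf[pf.roi_id == row.roi_id]
            assert not ((own.left_bin <= row.bin) & (row.bin <= own.right_bin)).any()

    def test_context_window_excludes_place_modulated_peak(self, small_session,
                                                          small_result):
        # equally large transients inside the BTSP field bounds are never
        # reported as solitary (forced by the exclusion rule)
        for s in small_result.solitary:
            assert s.amplitude >= s.reference


class TestConcordance:
    def test_proportional_maxima_r_one(self, small_session, small_result):
        ev = next(e for e in small_result.events if e.category == "BTSP")
        roi = ev.roi_id
        binned = small_result.binned
        fields = [f for f in small_result.place_fields if f.roi_id == roi]
        r, null = spike_fluorescence_concordance(
            small_result.dff[:, roi], binned, roi, fields
        )
        assert r > 0.8
        assert len(null) == binned.n_laps * len(fields)
        assert abs(np.mean(null)) < 0.25  # exchangeable laps -> null centred near 0

    def test_no_fields_rejected(self, small_result):
        with pytest.raises(ValueError):
            spike_fluorescence_concordance(
                small_result.dff[:, 0], small_result.binned, 0, []
            )
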