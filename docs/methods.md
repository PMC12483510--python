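# Methods

This note documents the analysis model implemented by `pffpipe`, its
defaults, the synthetic conditions it is validated under, and the design
choices taken where the procedure was genuinely underdetermined.

## Signal model and preprocessing

The pipeline consumes the standard outputs of a two-photon segmentation
suite: per-ROI raw fluorescence `F_raw`, neuropil fluorescence `F_neu`, and
non-negative deconvolved activity, frame-aligned with behavior (position,
speed, 1-based lap index) at ~31 Hz. Neuropil correction is
`F = F_raw − c·F_neu` with `c = 0.7` (configurable).

Deconvolved activity is treated conservatively: a non-zero sample at frame
`t` is kept only if its fluorescence transient is resolvable above noise.
The transient amplitude is `F_max − F_base`, where `F_max` averages the
three samples around the local maximum of `F` in frames `t..t+9`, and
`F_base` is the prediction at `t−20` of a linear fit over frames
`t−30..t−20` (11 samples, inclusive). The amplitude must exceed both the
fit RMSE (`SD_local`) and a per-ROI `SD_global`, the SD of `F` within
`[median·(1−1.5), median·(1+0.5)]`. The band phrase "1.5 times below and
0.5 times above the median" is ambiguous between multiples of the median
and of an SD; both interpretations are implemented
(`global_noise_band = "median_fraction" | "sd_units"`), the median-fraction
reading being the default. Events closer than 30 frames to the trace start
fall back to the available baseline prefix and are rejected below 5
samples; the peak search truncates at the trace end.

ΔF/F uses `F₀ =` rolling median of the *preceding* 1000 samples; the first
1000 frames use the *following* 1000 samples, and traces shorter than the
window use the whole-trace median. Frames with `F₀ ≤ 0` are flagged and
zeroed. Transient alignment for waveform averaging takes the maximum of the
4-sample lagged difference of a 5-point moving average (steepest rise),
extracts −50..+150 samples (201, NaN-padded at segment edges), and measures
each trace's peak as its value at the mean-trace maximum minus its own
window median.

## Spatial tuning and place fields

The 832-cm corridor is discretized into `floor(832/4.24) = 196` bins
(residual length joins the last bin; bins are 0-based with inclusive
bounds). Lap × bin cells with mean running speed < 4 cm/s are excluded from
all tuning statistics. Tuning curves are across-lap means of per-lap bin
means; ROIs need odd/even-curve Pearson r ≥ 0.25 (undefined correlations
excluded).

Skaggs information is computed in bits/event,
`SI = Σᵢ pᵢ (λᵢ/λ̄) log₂(λᵢ/λ̄)` with occupancy fractions `pᵢ`; bins with
zero rate contribute zero and `SI = 0` when `λ̄ = 0`. (Bits/event vs.
bits/second only rescales the statistic monotonically and cannot change a
percentile test.) Significance uses a null of 1500 iterations in which each
lap's activity is circularly shifted in time by an independent uniform
integer and everything is re-binned; an ROI is significant above the 99th
percentile. The shuffle is implemented sparsely (only non-zero samples are
moved), which makes the 1500-fold null cheap for gated activity.

Fields are peaks of height ≥ 6 (in a.u./frame of mean gated activity — the
threshold's unit is a choice, since only the number is prescribed) with
footprints at relative height 0.93 of the prominence, edges widened to
whole bins. Adjacent peaks merge when footprints overlap or the
intervening minimum exceeds half the larger peak; merging scans
left-to-right pairwise until stable and is idempotent. Each footprint,
extended by half its width on both sides, is tested with a local version of
the circular-shift null (95th percentile, shifts confined to the region's
frames); retained fields must contain ≥ 1 gated event on ≥ 30% of laps.

## Formation and categorization

Per field, a lap × bin matrix is built from frame-level activity floored at
64 a.u., with bounds extended 5 bins rightward (clipped at the corridor
end) and no speed filtering — forward-shifted formation bursts stay
visible. (The floor applies to frames *before* bin averaging, so matrix
entries can lie below 64; an entry-level floor would distort lap means.)

A lap qualifies as the formation lap if it is active, lies after lap 17
(1-based; configurable to 0 for novel-corridor extensions), and at most 10%
of all previous laps have a mean activity above 1% of its own. The field
ends before the first run of 5 silent laps or at the session end. If the
earliest qualifying candidate fails the subsequent filters — lifetime
`end − formation + 1 ≥ 9` laps; ≤ 8 laps below 10% of the peak lap maximum
— the scan resumes after that candidate's end lap, since later laps may
satisfy the stated formation rule in their own right (a single stray gated
event would otherwise veto a genuine formation a few laps later); if no
candidate survives, the first exclusion is reported.

Classification needs ≥ 3 active post-formation laps:

* **gain** — formation-lap peak > mean peak of the next three active laps;
* **backward shift** — mean of the smoothed COM (running average, kernel 3,
  centered, over the active-lap series) of the first three post-formation
  active laps < the formation-lap raw COM;
* **drift** — on the smoothed COM from the 4th post-formation active lap:
  OLS regression back-extrapolated to the first post-formation active lap
  exceeds the formation location *and* Spearman ρ < 0 with p < 0.05.

`gain ∧ shift ∧ ¬drift → BTSP`; `¬gain ∧ ¬shift → NON_BTSP` (drift
irrelevant); the remaining combinations map to
`EXCLUDED_DRIFT / EXCLUDED_GAIN_NO_SHIFT / EXCLUDED_NOSHIFT_ONLY_PARTIAL`,
with `EXCLUDED_SHORT / EXCLUDED_INCONSISTENT` for the filters. All strict
inequalities carry a 10⁻⁹ relative guard so that exactly tied quantities
(e.g. the smoothed COM of a constant series, which can differ from it by
one ULP) do not flip a flag; classification is therefore exactly
scale-invariant. "Active lap" means ≥ 1 non-zero floored entry; the
10%-of-peak rule is used only for silent-lap counting. Formation-lap mean
activity averages over all matrix bins including zeros (the alternative,
active-bins-only, rescales both sides of the 1% rule similarly).

The misclassification bootstrap masks laps from a non-BTSP event's
formation onward until re-detection yields a BTSP-like event or the field
ends; absent a hidden signature the transformation probability is 0.
Otherwise the test area (non-BTSP start → hidden BTSP formation) is scored
by mean activity and active-lap fraction against 1000 equal-sized segments
sampled uniformly over (ROI, lap window, bin window) placements outside all
place fields; the event is unlikely-misclassified when < 5% of null
segments are ≥ on both metrics.

Solitary transients are sought in ROIs owning a BTSP event: ΔF/F peaks
(prominence ≥ 1, separation ≥ 20 samples) at least as large as the
formation-lap maximum ΔF/F over the field extended 5 bins rightward (the
smallest reference if several BTSP events), outside all of the ROI's
fields, with context (±5 laps, 11 centered bins, peak lap excluded) below
the ROI's session median + 2 SD of ΔF/F. Only the largest peak per ROI is
reported; ties break to the earliest lap.

## Population and width analyses

PV correlograms use non-thresholded binned mean activity: per bin the
across-ROI vectors of each lap pair are Pearson-correlated and averaged
over bins with defined correlations (zero-variance bins are skipped for
that pair, not imputed as 0; the skipped count is reported).
`locate_switch` maximizes within-block minus between-block mean correlation
over split laps and reports none below a 0.2 contrast — it is a convenience
localizer for a structure that is otherwise judged visually, not a
published criterion. Odd/even PV correlations across matched 6-m corridor
segments support extension experiments.

Field width is modelled as a linear (Gaussian, identity-link) function of
formation-lap running speed and the along-track distance to the nearest
landmark centroid (the corridor is 1-D, so Euclidean distance reduces to
`|x − centroid|`; the field's center anchors the distance). Events with
formation speed < 5 cm/s or bounds touching the corridor ends are excluded.
Explained variance is `1 − MSE_LOO/var(width)` with exact leave-one-out
predictions via the hat-matrix identity (verified in tests against naive
per-event refits). The subjective corridor start is optimized on a 1-cm
grid over the first 50 cm by maximizing the combined-model EV (ties to the
smallest offset). The BTSP-vs-comparison contrast subsamples the BTSP set
to the comparison size 10,000 times and reports 95% CIs of Spearman (r, p).

QC images: per-pixel mean Pearson correlation with the 8 nearest neighbors
(edge pixels use available neighbors; constant pixels map to 0), sigmoid
contrast (cutoff 0.8, gain 20); and a temporal-COM pseudo-color
(`Σ t·I(t)/Σ I(t)`, cyclic colormap, neutral gray at zero mass). These are
visual aids; accept/reject remains a human decision.

## Synthetic study conditions

`SessionConfig` defaults define the conditions all validation runs use:
200 ROIs × 60 laps at ~31 Hz, session mean speed drawn from 30–40 cm/s with
4% lap and frame jitter and a slow-down ramp before the reward zone
(760–832 cm); six landmarks; 15 BTSP-like, 12 non-BTSP-like, 4 drifting,
and 40 pre-existing fields plus 8 solitary transients; background
deconvolution chatter at 0.005 Hz/ROI with lognormal amplitudes (median
30 a.u., σ = 0.5 — mostly below the 64 a.u. floor, occasionally above,
which exercises the floor and the formation re-scan). Implants are
calibrated to 150–800 a.u. so the absolute 64 a.u. threshold is meaningful;
formation bursts 400–800 a.u., post-formation events 150–300 a.u. with 5%
lap jitter. The forward model is a peak-normalized double-exponential
kernel (rise 0.18 s, decay 1.8 s, GCaMP6s-like), baseline 300 a.u.,
0.005 ΔF/F per a.u., additive Gaussian noise (SD 15 a.u.), and a shared
low-pass neuropil signal mixed at 0.7 into `F_raw` so the stated correction
is exact in expectation.

Implant windows snap to spatial-bin edges (2 bins wide), making the binned
COM of a field exactly lap-invariant; BTSP formation bursts sit 1–3 bins
forward of the stable center (the implanted backward shift), drifting
implants follow an accelerating backward trajectory from slightly forward
of the formation site (the phenotype the drift rule is built to catch), and
non-BTSP events appear with a 0.8× formation-lap amplitude and a constant
center. The last choice encodes "no gain, no backward shift" robustly: the
classifier's strict inequalities on exactly-tied quantities would otherwise
be decided by noise, which is a property of the boundary case, not of the
detector.

**What passing these conditions shows — and does not.** The generator
exercises the full decision chain (gating, binning, shuffles, demarcation,
categorization, bootstrap, solitary context) under controlled truth, so it
validates the *rules* and their implementation. It does not emulate slow
calcium-indicator saturation, motion artifacts, overlapping ROIs, bursty
non-Poisson background, or real COM jitter of biological fields, so
recovery rates here are upper bounds on real-data performance, and the
package makes no claim about event counts in any real dataset.

## Problem sizes and numerics

Validation uses 2 full-scale sessions in the test suite and 4 in
`scripts/acceptance.py` (the generator and pipeline take ~1.5 min per
session on one CPU), 500 untuned cells for the 1% shuffle calibration, 400
resampled areas for the bootstrap calibration, and 30–50 seeds for the
explained-variance recovery at n = 300. All randomness flows from one root
seed through `numpy.random.SeedSequence` spawning, per stage and per ROI,
so every result bundle is byte-identical across runs (HDF5 is written with
`track_times=False` for the same reason). Oracle-equivalence tests hold to
≤ 10⁻¹⁰ relative error; closed forms (uniform tuning → 0 bits, single bin
of K → log₂K, constant trace → ΔF/F ≡ 0) hold to machine precision.

## Known limitations

* The bootstrap's null requires enough outside-field area; sessions tiled
  densely with fields raise an explicit error rather than degrading.
* `locate_switch` assumes a single switch; multi-switch sessions return
  the dominant split only.
* The bits/event vs. bits/second ambiguity and the global-noise band
  interpretation are exposed as configuration, not resolved empirically.
* Drift detection needs ≥ 3 smoothed COM samples beyond the 4th
  post-formation active lap; shorter fields cannot be flagged as drifting.
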