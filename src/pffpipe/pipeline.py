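"""End-to-end pipeline: session in, event tables and correlograms out.

Stage order follows the analysis procedure: neuropil correction -> event
gating -> dF/F -> spatial binning -> odd/even reliability -> Skaggs
significance -> place-field demarcation -> temporal demarcation and
BTSP / non-BTSP categorization -> misclassification bootstrap -> solitary
events -> population-vector correlogram -> width model. All randomness is
derived from ``cfg.seed``, so a fixed (config, session) pair reproduces the
result bundle exactly.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from . import dynamics, population, preprocess, tuning, width
from .config import PipelineConfig
from .session import SessionData

logger = logging.getLogger("pffpipe")

__all__ = ["PipelineResult", "run_pipeline"]


@dataclass
class PipelineResult:
    """Bundle of all pipeline outputs for one session."""

    gate_report: pd.DataFrame
    tuning_table: pd.DataFrame          # per ROI: oddeven_r, SI, significance
    place_fields: list                  # tuning.PlaceField
    place_field_table: pd.DataFrame
    events: list                        # dynamics.PFFEvent
    event_table: pd.DataFrame
    solitary: list                      # dynamics.SolitaryEvent
    solitary_table: pd.DataFrame
    correlogram: population.PVCorrelogram
    switch_lap: Optional[int]
    switch_contrast: float
    concordance_table: pd.DataFrame
    ev_reports: dict
    counts: dict
    binned: tuning.BinnedSession = None
    dff: np.ndarray = None

    def save(self, out_dir: str | Path) -> Path:
        """Write the bundle as CSV/JSON/NPY files (documented layout)."""
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        self.gate_report.to_csv(out / "gate_report.csv", index=False)
        self.tuning_table.to_csv(out / "tuning.csv", index=False)
        self.place_field_table.to_csv(out / "place_fields.csv", index=False)
        self.event_table.to_csv(out / "events.csv", index=False)
        with open(out / "events.jsonl", "w") as fh:
            for _, row in self.event_table.iterrows():
                fh.write(json.dumps({k: _jsonable(v) for k, v in row.items()}) + "\n")
        self.solitary_table.to_csv(out / "solitary_events.csv", index=False)
        np.save(out / "pv_correlogram.npy", self.correlogram.matrix)
        self.concordance_table.to_csv(out / "concordance.csv", index=False)
        with open(out / "summary.json", "w") as fh:
            json.dump(
                {
                    "counts": self.counts,
                    "switch_lap": self.switch_lap,
                    "switch_contrast": self.switch_contrast,
                    "ev_reports": {
                        k: {kk: _jsonable(vv) for kk, vv in v.items()}
                        for k, v in self.ev_reports.items()
                    },
                },
                fh,
                indent=1,
                sort_keys=True,
            )
        return out


def _jsonable(v):
    if isinstance(v, (np.integer,)):
        return int(v)
    if isinstance(v, (np.floating,)):
        return None if np.isnan(v) else float(v)
    if isinstance(v, (np.bool_,)):
        return bool(v)
    if isinstance(v, float) and np.isnan(v):
        return None
    return v


def run_pipeline(
    session: SessionData,
    cfg: Optional[PipelineConfig] = None,
    *,
    do_bootstrap: bool = True,
    do_concordance: bool = True,
    do_width: bool = True,
    optimize_offset: bool = False,
) -> PipelineResult:
    cfg = cfg or PipelineConfig()
    spec = session.corridor
    behavior = session.behavior
    ss = np.random.SeedSequence(cfg.seed)
    seed_sig, seed_dem, seed_boot = (
        int(s.generate_state(1)[0] % 2**31) for s in ss.spawn(3)
    )

    # --- preprocessing -----------------------------------------------------
    F = preprocess.neuropil_correct(session.F_raw, session.F_neu, cfg.neuropil_coefficient)
    gated, gate_report = preprocess.gate_inferred_events(F, session.deconvolved, cfg)
    dff = preprocess.compute_dff(F, cfg.dff_window).dff
    logger.info("gate: %d/%d candidates accepted",
                int(gate_report.accepted.sum()), len(gate_report))

    # --- binning and tuning ------------------------------------------------
    binned = tuning.bin_session(behavior, gated, spec, cfg)
    curves = tuning.tuning_curves(binned)
    oe = tuning.oddeven_reliability(binned, cfg)

    engine = tuning._session_null(binned)
    si_vals = np.full(session.n_rois, np.nan)
    significant = np.zeros(session.n_rois, dtype=bool)
    candidates = [
        int(r) for r in oe[oe.keep].roi_id if np.any(gated[:, int(r)] > 0)
    ]
    for roi in candidates:
        sig, si, _ = tuning.assess_spatial_significance(
            binned, gated, roi, cfg=cfg, seed=seed_sig + roi, null=engine
        )
        si_vals[roi], significant[roi] = si, sig
    tuning_table = oe.assign(skaggs_bits=si_vals, significant=significant)
    logger.info("tuning: %d/%d ROIs kept by odd/even r, %d spatially significant",
                int(oe.keep.sum()), session.n_rois, int(significant.sum()))

    # --- place-field demarcation ------------------------------------------
    fields: list[tuning.PlaceField] = []
    fields_by_roi: dict[int, list[tuning.PlaceField]] = {}
    for roi in np.flatnonzero(significant):
        roi = int(roi)
        pfs = tuning.demarcate_place_fields(
            curves[:, roi], binned, gated, roi, cfg=cfg, seed=seed_dem + roi
        )
        if pfs:
            fields_by_roi[roi] = pfs
            fields.extend(pfs)
    place_field_table = pd.DataFrame(
        [
            dict(
                roi_id=pf.roi_id, left_bin=pf.bounds[0], right_bin=pf.bounds[1],
                ext_left_bin=pf.extended_bounds[0], ext_right_bin=pf.extended_bounds[1],
                width_cm=pf.width_cm, peak_bin=pf.peak_bin, peak_height=pf.peak_height,
                active_lap_fraction=pf.active_lap_fraction,
            )
            for pf in fields
        ],
        columns=["roi_id", "left_bin", "right_bin", "ext_left_bin", "ext_right_bin",
                 "width_cm", "peak_bin", "peak_height", "active_lap_fraction"],
    )
    logger.info("demarcation: %d place fields on %d ROIs", len(fields), len(fields_by_roi))

    # --- temporal demarcation and categorization ---------------------------
    floored = gated.copy()
    floored[floored < cfg.activity_floor_au] = 0.0
    binned_thresh = tuning.bin_session(behavior, floored, spec, cfg).activity

    events: list[dynamics.PFFEvent] = []
    matrices: dict[int, dynamics.PFActivityMatrix] = {}
    for i, pf in enumerate(fields):
        pfmat = dynamics.build_pf_activity_matrix(binned, gated[:, pf.roi_id], pf, cfg)
        # scan formation candidates; a candidate that fails the lifetime or
        # consistency filter (e.g. one stray gated event) does not preclude
        # a later lap that itself satisfies the formation rule
        ev = None
        search_from = 1
        while search_from <= binned.n_laps:
            formation, end = dynamics.find_formation_and_end(
                pfmat, cfg, search_from_lap=search_from
            )
            if formation is None:
                break
            keep, reason = dynamics.apply_pf_filters(pfmat, formation, end, cfg)
            if keep:
                ev = dynamics.classify_pff(pfmat, formation, end, cfg)
                break
            if ev is None:  # remember the first exclusion for reporting
                ev = dynamics.PFFEvent(
                    roi_id=pf.roi_id, place_field=pf, formation_lap=formation,
                    end_lap=end, gain=False, backward_shift=False, drift=False,
                    category=reason,
                )
            search_from = end + 1
        if ev is None:
            continue
        formation = ev.formation_lap
        ev.place_field = pf
        lap_sel = (
            (binned.frame_lap0 == formation - 1)
            & (binned.frame_bin >= pfmat.bins[0])
            & (binned.frame_bin <= pfmat.bins[1])
        )
        if lap_sel.any():
            ev.formation_speed_cm_s = float(behavior.speed_cm_s[lap_sel].mean())
        events.append(ev)
        matrices[id(ev)] = pfmat

    # --- misclassification bootstrap ---------------------------------------
    pf_bounds = {r: [pf.bounds for pf in pfs] for r, pfs in fields_by_roi.items()}
    boot_prob = {}
    boot_flag = {}
    if do_bootstrap:
        for i, ev in enumerate(events):
            if ev.category != "NON_BTSP":
                continue
            try:
                prob, flag = dynamics.misclassification_bootstrap(
                    ev, matrices[id(ev)], binned_thresh, pf_bounds, cfg,
                    seed=seed_boot + i,
                )
            except ValueError as exc:
                logger.warning("bootstrap skipped for ROI %d: %s", ev.roi_id, exc)
                continue
            boot_prob[id(ev)], boot_flag[id(ev)] = prob, flag

    event_table = pd.DataFrame(
        [
            dict(
                roi_id=ev.roi_id,
                category=ev.category,
                formation_lap=ev.formation_lap,
                end_lap=ev.end_lap,
                gain=ev.gain,
                backward_shift=ev.backward_shift,
                drift=ev.drift,
                formation_location_cm=ev.formation_location_cm,
                formation_amplitude=ev.formation_amplitude,
                formation_speed_cm_s=ev.formation_speed_cm_s,
                left_bin=ev.place_field.bounds[0],
                right_bin=ev.place_field.bounds[1],
                width_cm=ev.place_field.width_cm,
                center_cm=(ev.place_field.bounds[0] + ev.place_field.bounds[1] + 1)
                / 2.0 * binned.bin_width_cm,
                bootstrap_probability=boot_prob.get(id(ev), np.nan),
                unlikely_misclassified=boot_flag.get(id(ev), None),
            )
            for ev in events
        ],
        columns=["roi_id", "category", "formation_lap", "end_lap", "gain",
                 "backward_shift", "drift", "formation_location_cm",
                 "formation_amplitude", "formation_speed_cm_s", "left_bin",
                 "right_bin", "width_cm", "center_cm", "bootstrap_probability",
                 "unlikely_misclassified"],
    )

    # --- solitary events ----------------------------------------------------
    solitary = dynamics.detect_solitary_events(dff, binned, events, fields_by_roi, cfg)
    solitary_table = pd.DataFrame(
        [
            dict(roi_id=s.roi_id, lap=s.lap, bin=s.bin, frame=s.frame,
                 amplitude=s.amplitude, reference=s.reference)
            for s in solitary
        ],
        columns=["roi_id", "lap", "bin", "frame", "amplitude", "reference"],
    )

    # --- population ---------------------------------------------------------
    correlogram = population.pv_correlogram(binned.activity)
    try:
        switch_lap, contrast = population.locate_switch(correlogram, cfg)
    except ValueError:
        switch_lap, contrast = None, np.nan

    # --- spike/fluorescence concordance ------------------------------------
    conc_rows = []
    if do_concordance:
        new_pf_rois = sorted({ev.roi_id for ev in events})
        for roi in new_pf_rois:
            r, null = dynamics.spike_fluorescence_concordance(
                dff[:, roi], binned, roi, fields_by_roi.get(roi, [])
            )
            p = float(np.mean(null >= r)) if len(null) else np.nan
            conc_rows.append(dict(roi_id=roi, pearson_r=r, null_p=p,
                                  n_permutations=len(null)))
    concordance_table = pd.DataFrame(
        conc_rows, columns=["roi_id", "pearson_r", "null_p", "n_permutations"]
    )

    # --- width model ---------------------------------------------------------
    ev_reports: dict = {}
    if do_width:
        retained = event_table[event_table.category.isin(["BTSP", "NON_BTSP"])]
        if len(retained) >= 5:
            dataset = width.build_width_dataset(retained, spec, cfg)
            try:
                for preds in (("speed",), ("cue_distance",), ("speed", "cue_distance")):
                    rep = width.loo_explained_variance(dataset, preds, cfg)
                    ev_reports["+".join(preds)] = dict(
                        explained_variance=rep.explained_variance,
                        n=rep.n, warning=rep.warning,
                    )
                if optimize_offset:
                    best, curve = width.optimize_start_offset(retained, spec, cfg)
                    ev_reports["best_start_offset_cm"] = dict(offset=best)
            except ValueError as exc:
                logger.warning("width model skipped: %s", exc)

    by_cat = event_table.category.value_counts().to_dict() if len(event_table) else {}
    counts = {
        "n_rois": int(session.n_rois),
        "n_gate_candidates": int(len(gate_report)),
        "n_gate_accepted": int(gate_report.accepted.sum()),
        "n_oddeven_kept": int(oe.keep.sum()),
        "n_significant": int(significant.sum()),
        "n_place_fields": len(fields),
        "n_pff_events": len(events),
        "n_solitary": len(solitary),
        "events_by_category": {k: int(v) for k, v in sorted(by_cat.items())},
    }
    logger.info("events: %s", counts["events_by_category"])

    return PipelineResult(
        gate_report=gate_report,
        tuning_table=tuning_table,
        place_fields=fields,
        place_field_table=place_field_table,
        events=events,
        event_table=event_table,
        solitary=solitary,
        solitary_table=solitary_table,
        correlogram=correlogram,
        switch_lap=switch_lap,
        switch_contrast=contrast,
        concordance_table=concordance_table,
        ev_reports=ev_reports,
        counts=counts,
        binned=binned,
        dff=dff,
    )
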