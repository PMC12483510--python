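"""Place-field width as a function of running speed and landmark distance.

Widths of newly formed fields are modelled with ordinary linear regression
(Gaussian GLM, identity link) on the formation-lap running speed and the
along-track distance to the nearest visual landmark; prediction quality is
the leave-one-out cross-validated explained-variance fraction
``EV = 1 - LOO MSE / var(width)``. Because the corridor is one-dimensional,
the Euclidean distance to a landmark centroid reduces to the absolute
along-track distance.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .config import CorridorSpec, PipelineConfig

__all__ = [
    "build_width_dataset",
    "cue_distance",
    "EVReport",
    "loo_explained_variance",
    "optimize_start_offset",
    "subsample_regression_comparison",
]

PREDICTORS = ("speed", "cue_distance")


def cue_distance(
    position_cm: np.ndarray,
    landmarks_cm: Sequence[float],
    start_offset_cm: float = 0.0,
) -> np.ndarray:
    """Along-track distance to the nearest landmark centroid.

    ``start_offset_cm`` shifts the animal's subjective corridor start: the
    effective landmark positions become ``centroid + offset``.
    """
    landmarks = np.asarray(landmarks_cm, dtype=np.float64)
    if landmarks.size == 0:
        raise ValueError("at least one landmark is required")
    pos = np.atleast_1d(np.asarray(position_cm, dtype=np.float64))
    d = np.abs(pos[:, None] - (landmarks[None, :] + start_offset_cm))
    return d.min(axis=1)


def build_width_dataset(
    events: pd.DataFrame,
    spec: CorridorSpec,
    cfg: Optional[PipelineConfig] = None,
    start_offset_cm: float = 0.0,
) -> pd.DataFrame:
    """Assemble the width-model dataset from a PFF event table.

    ``events`` needs columns ``width_cm``, ``formation_speed_cm_s``,
    ``center_cm``, ``left_bin``, ``right_bin`` (and optionally
    ``category``). Events are excluded (flagged, not dropped) when the
    formation-lap speed is below 5 cm/s or the field's bounds touch the
    corridor start or end (truncated widths).
    """
    cfg = cfg or PipelineConfig()
    df = events.copy()
    df["speed_cm_s"] = df["formation_speed_cm_s"]
    df["cue_distance_cm"] = cue_distance(
        df["center_cm"].to_numpy(), spec.landmark_centroids_cm, start_offset_cm
    )
    slow = df["formation_speed_cm_s"] < cfg.min_formation_speed_cm_s
    edge = (df["left_bin"] <= 0) | (df["right_bin"] >= spec.n_bins - 1)
    df["excluded"] = slow | edge
    df["exclusion_reason"] = np.select(
        [slow & edge, slow, edge],
        ["low_speed+edge", "low_speed", "edge"],
        default="",
    )
    return df


@dataclass
class EVReport:
    """Leave-one-out explained variance of a width model."""

    predictors: tuple[str, ...]
    explained_variance: float
    loo_mse: float
    width_variance: float
    predictions: np.ndarray
    n: int
    start_offset_cm: float = 0.0
    warning: Optional[str] = None


def _loo_predictions(X: np.ndarray, y: np.ndarray) -> np.ndarray:
    """Exact leave-one-out predictions of an OLS fit via the hat matrix."""
    Xd = np.column_stack([np.ones(len(y)), X])
    beta, *_ = np.linalg.lstsq(Xd, y, rcond=None)
    fitted = Xd @ beta
    # h_ii from the pseudoinverse; LOO residual = residual / (1 - h_ii)
    G = np.linalg.pinv(Xd.T @ Xd)
    h = np.einsum("ij,jk,ik->i", Xd, G, Xd)
    resid = y - fitted
    with np.errstate(divide="ignore", invalid="ignore"):
        loo_resid = resid / (1.0 - h)
    return y - loo_resid


def loo_explained_variance(
    dataset: pd.DataFrame,
    predictors: Sequence[str] = PREDICTORS,
    cfg: Optional[PipelineConfig] = None,
) -> EVReport:
    """EV fraction of width predicted by speed, cue distance, or both.

    ``EV = 1 - MSE_LOO / var(width)`` with ordinary least squares (identity
    link) refit for each left-out event; computed here with the exact
    hat-matrix identity.
    """
    cols = {"speed": "speed_cm_s", "cue_distance": "cue_distance_cm"}
    bad = [p for p in predictors if p not in cols]
    if bad:
        raise ValueError(f"unknown predictors {bad}; choose from {list(cols)}")
    df = dataset[~dataset["excluded"]] if "excluded" in dataset else dataset
    y = df["width_cm"].to_numpy(dtype=np.float64)
    if len(y) < 3:
        raise ValueError(f"need at least 3 retained events, got {len(y)}")
    X = df[[cols[p] for p in predictors]].to_numpy(dtype=np.float64)
    warning = None
    if np.any(X.std(axis=0) == 0):
        warning = "degenerate predictor with zero variance"
    pred = _loo_predictions(X, y)
    mse = float(np.mean((y - pred) ** 2))
    var = float(np.var(y))
    ev = 1.0 - mse / var if var > 0 else np.nan
    return EVReport(
        predictors=tuple(predictors),
        explained_variance=ev,
        loo_mse=mse,
        width_variance=var,
        predictions=pred,
        n=len(y),
        warning=warning,
    )


def optimize_start_offset(
    events: pd.DataFrame,
    spec: CorridorSpec,
    cfg: Optional[PipelineConfig] = None,
    predictors: Sequence[str] = PREDICTORS,
) -> tuple[float, pd.DataFrame]:
    """Grid-search the subjective corridor start within the first 50 cm.

    Rebuilds the dataset at each candidate offset and keeps the one
    maximizing the combined-model LOO explained variance (ties go to the
    smallest offset). Returns the best offset and the full EV curve.
    """
    cfg = cfg or PipelineConfig()
    lo, hi = cfg.offset_range_cm
    if cfg.offset_step_cm <= 0:
        raise ValueError("offset step must be positive")
    offsets = np.arange(lo, hi + 0.5 * cfg.offset_step_cm, cfg.offset_step_cm)
    rows = []
    for off in offsets:
        ds = build_width_dataset(events, spec, cfg, start_offset_cm=float(off))
        rep = loo_explained_variance(ds, predictors, cfg)
        rows.append(dict(offset_cm=float(off), explained_variance=rep.explained_variance))
    curve = pd.DataFrame(rows)
    best = curve.loc[curve["explained_variance"].idxmax(), "offset_cm"]
    # ties -> smallest offset
    top = curve[curve["explained_variance"] == curve["explained_variance"].max()]
    best = float(top["offset_cm"].min())
    return best, curve


def subsample_regression_comparison(
    btsp_widths: np.ndarray,
    btsp_speeds: np.ndarray,
    n_target: int,
    comparison: Optional[tuple[float, float]] = None,
    n_resamples: int = 10000,
    seed: int = 0,
) -> dict:
    """Subsample the BTSP events to a comparison sample size, 10,000 times.

    Each resample draws ``n_target`` BTSP events without replacement and
    computes the Spearman correlation (r, p) of width vs speed; the 95% CIs
    of both are reported, with a verdict for an optional comparison (r, p)
    pair (e.g. the non-BTSP group's values): ``True`` when the comparison
    falls outside the CI.
    """
    w = np.asarray(btsp_widths, dtype=np.float64)
    s = np.asarray(btsp_speeds, dtype=np.float64)
    if n_target < 3:
        raise ValueError("n_target must be >= 3")
    if n_target > len(w):
        raise ValueError(f"n_target {n_target} exceeds BTSP sample size {len(w)}")
    rng = np.random.default_rng(seed)
    rs = np.empty(n_resamples)
    ps = np.empty(n_resamples)
    for i in range(n_resamples):
        idx = rng.choice(len(w), size=n_target, replace=False)
        rs[i], ps[i] = spearmanr(w[idx], s[idx])
    r_ci = tuple(np.percentile(rs, [2.5, 97.5]))
    p_ci = tuple(np.percentile(ps, [2.5, 97.5]))
    out = dict(r_ci=r_ci, p_ci=p_ci, r_samples=rs, p_samples=ps)
    if comparison is not None:
        r_c, p_c = comparison
        out["verdict_outside_ci"] = bool(
            not (r_ci[0] <= r_c <= r_ci[1]) or not (p_ci[0] <= p_c <= p_ci[1])
        )
    return out
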