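"""Population-vector correlation analyses across laps and corridor segments."""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .config import PipelineConfig

__all__ = ["PVCorrelogram", "pv_correlogram", "oddeven_pv_extension", "locate_switch"]


@dataclass
class PVCorrelogram:
    """laps x laps matrix of bin-averaged across-ROI Pearson correlations."""

    matrix: np.ndarray
    n_defined_bins: np.ndarray  # per lap pair, bins contributing a defined r

    @property
    def n_laps(self) -> int:
        return self.matrix.shape[0]


def _standardize_rows(X: np.ndarray) -> np.ndarray:
    """Rows to zero mean / unit norm; zero-variance rows become NaN."""
    mu = X.mean(axis=1, keepdims=True)
    Z = X - mu
    norm = np.linalg.norm(Z, axis=1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = Z / norm
    Z[np.squeeze(norm, axis=1) == 0] = np.nan
    return Z


def pv_correlogram(activity: np.ndarray) -> PVCorrelogram:
    """Lap-by-lap population-vector correlogram.

    ``activity`` is a laps x bins x ROIs tensor of non-thresholded mean
    inferred activity. For every spatial bin the across-ROI activity vectors
    of each lap pair are Pearson-correlated; the correlogram entry is the
    mean over bins with a defined correlation (bins where either lap's
    vector has zero variance are skipped for that pair, not imputed).
    """
    activity = np.asarray(activity, dtype=np.float64)
    if activity.ndim != 3:
        raise ValueError("activity must be laps x bins x ROIs")
    n_laps, n_bins, n_rois = activity.shape
    if n_laps < 2 or n_rois < 2:
        raise ValueError("need at least 2 laps and 2 ROIs")
    acc = np.zeros((n_laps, n_laps))
    cnt = np.zeros((n_laps, n_laps), dtype=np.int64)
    for b in range(n_bins):
        Z = _standardize_rows(activity[:, b, :])        # laps x rois
        C = Z @ Z.T
        ok = np.isfinite(C)
        acc[ok] += C[ok]
        cnt += ok
    with np.errstate(invalid="ignore"):
        M = np.where(cnt > 0, acc / cnt, np.nan)
    return PVCorrelogram(matrix=M, n_defined_bins=cnt)


def oddeven_pv_extension(
    original: np.ndarray,
    extension: np.ndarray,
) -> tuple[float, float, float]:
    """Odd/even-lap PV correlations within and across two corridor segments.

    Both inputs are laps x bins x ROIs activity tensors over matching-length
    segments (e.g. the first 6 m of the familiar corridor, reward zone
    excluded, and the 6-m novel extension). Per ROI and bin the mean
    activity over odd and over even laps forms the population vectors;
    per-bin across-ROI Pearson correlations are averaged over defined bins.

    Returns ``(orig odd-even, orig odd vs extension even, ext odd-even)``.
    """
    original = np.asarray(original, dtype=np.float64)
    extension = np.asarray(extension, dtype=np.float64)
    if original.shape[1] != extension.shape[1]:
        raise ValueError(
            f"segment bin counts differ: {original.shape[1]} vs {extension.shape[1]}"
        )
    if original.shape[2] != extension.shape[2]:
        raise ValueError("sessions must share the ROI population")

    def oe(t):
        odd = t[0::2].mean(axis=0)   # bins x rois  (1-based odd laps)
        even = t[1::2].mean(axis=0)
        return odd, even

    o_odd, o_even = oe(original)
    e_odd, e_even = oe(extension)

    def mean_r(A, B):
        rs = []
        for b in range(A.shape[0]):
            a, v = A[b], B[b]
            if a.std() == 0 or v.std() == 0:
                continue
            rs.append(np.corrcoef(a, v)[0, 1])
        return float(np.mean(rs)) if rs else np.nan

    return mean_r(o_odd, o_even), mean_r(o_odd, e_even), mean_r(e_odd, e_even)


def locate_switch(
    correlogram: PVCorrelogram,
    cfg: Optional[PipelineConfig] = None,
) -> tuple[Optional[int], float]:
    """Locate an abrupt representational switch in a PV correlogram.

    Scans candidate split laps and maximizes the two-block contrast (mean
    within-block off-diagonal correlation minus mean between-block
    correlation). Returns ``(first lap of the second block, contrast)``
    (1-based), or ``(None, contrast)`` when the best contrast stays below
    the configured threshold. This is a convenience localizer for switches
    that are otherwise identified visually.
    """
    cfg = cfg or PipelineConfig()
    M = correlogram.matrix
    n = M.shape[0]
    if n < 6:
        raise ValueError("need at least 6 laps to locate a switch")
    off = ~np.eye(n, dtype=bool)
    best_lap, best_contrast = None, -np.inf
    for k in range(2, n - 1):  # second block starts at 0-based lap k
        within = np.concatenate(
            [M[:k, :k][off[:k, :k]], M[k:, k:][off[: n - k, : n - k]]]
        )
        between = M[:k, k:].ravel()
        contrast = np.nanmean(within) - np.nanmean(between)
        if np.isfinite(contrast) and contrast > best_contrast:
            best_contrast = float(contrast)
            best_lap = k + 1
    if best_contrast < cfg.switch_contrast_threshold:
        return None, best_contrast
    return best_lap, best_contrast
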