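"""Pixel-level QC images for verifying single-cell origin of transients.

Local-coherence maps highlight pixels whose time series correlate with
their neighbors (i.e. belong to one active cell); temporal-COM
pseudo-coloring reveals whether subregions of a putative ROI are active at
different times, the tell-tale of merged cells. Both are visual aids for
human inspection, not automated accept/reject tests.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from matplotlib import colormaps
from skimage import exposure

__all__ = ["CoherenceImage", "local_coherence_image", "temporal_com_pseudocolor"]


@dataclass
class CoherenceImage:
    """Per-pixel neighbor coherence with contrast-adjusted grayscale."""

    coherence: np.ndarray  # H x W, mean neighbor Pearson r (undefined -> 0)
    grayscale: np.ndarray  # H x W in [0, 1], sigmoid contrast applied
    cutoff: float
    gain: float


_NEIGHBOR_OFFSETS = [
    (dy, dx) for dy in (-1, 0, 1) for dx in (-1, 0, 1) if (dy, dx) != (0, 0)
]


def local_coherence_image(
    movie: np.ndarray, cutoff: float = 0.8, gain: float = 20.0
) -> CoherenceImage:
    """Mean Pearson correlation of each pixel with its 8 nearest neighbors.

    Edge pixels average over their existing neighbors; pixels with a
    constant time series (or only constant neighbors) get coherence 0.
    The grayscale channel applies sigmoid contrast (``cutoff``/``gain``)
    to the coherence clipped into [0, 1].
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3 or movie.shape[0] < 2:
        raise ValueError("movie must be frames x H x W with at least 2 frames")
    T, H, W = movie.shape
    Z = movie - movie.mean(axis=0)
    norm = np.sqrt((Z**2).sum(axis=0))
    with np.errstate(invalid="ignore", divide="ignore"):
        Z = np.where(norm > 0, Z / norm, 0.0)
    defined = norm > 0

    acc = np.zeros((H, W))
    cnt = np.zeros((H, W))
    for dy, dx in _NEIGHBOR_OFFSETS:
        ys = slice(max(dy, 0), H + min(dy, 0))
        yn = slice(max(-dy, 0), H + min(-dy, 0))
        xs = slice(max(dx, 0), W + min(dx, 0))
        xn = slice(max(-dx, 0), W + min(-dx, 0))
        r = (Z[:, ys, xs] * Z[:, yn, xn]).sum(axis=0)
        both = defined[ys, xs] & defined[yn, xn]
        acc[ys, xs] += np.where(both, r, 0.0)
        cnt[ys, xs] += both
    with np.errstate(invalid="ignore"):
        coherence = np.where(cnt > 0, acc / np.maximum(cnt, 1), 0.0)
    coherence[~defined] = 0.0

    gray = exposure.adjust_sigmoid(np.clip(coherence, 0.0, 1.0), cutoff=cutoff, gain=gain)
    return CoherenceImage(coherence=coherence, grayscale=gray, cutoff=cutoff, gain=gain)


def temporal_com_pseudocolor(
    movie: np.ndarray, cmap: str = "hsv"
) -> tuple[np.ndarray, np.ndarray]:
    """Per-pixel temporal center of mass of intensity, mapped to hue.

    ``COM = sum_t t * I(t) / sum_t I(t)`` per pixel (frame units); pixels
    with zero total intensity are NaN in the COM map and neutral gray in
    the RGB rendering. Intensities must be non-negative (offset-subtracted).

    Returns ``(com, rgb)``.
    """
    movie = np.asarray(movie, dtype=np.float64)
    if movie.ndim != 3:
        raise ValueError("movie must be frames x H x W")
    if np.any(movie < 0):
        raise ValueError("intensities must be non-negative")
    T = movie.shape[0]
    t = np.arange(T, dtype=np.float64)
    total = movie.sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        com = np.einsum("t,thw->hw", t, movie) / total
    com[total == 0] = np.nan

    cm = colormaps[cmap]
    frac = np.nan_to_num(com / max(T - 1, 1), nan=0.0)
    rgb = np.asarray(cm(frac))[..., :3]
    rgb[np.isnan(com)] = 0.5  # neutral gray
    return com, rgb
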