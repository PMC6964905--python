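"""Automatic grey-level thresholds.

Two histogram-based thresholds used across the pipelines:

* :func:`moments_threshold` — Tsai's moment-preserving selection (the
  "Moments" auto-threshold).  The grey-level histogram is replaced by a
  two-level distribution {z0 with fraction p0, z1 with fraction 1-p0}
  constrained to preserve the first three moments of the grey image; the
  threshold is placed at the p0-tile of the cumulative histogram.
* :func:`intermeans_threshold` — the iterative intermeans fixed point
  (the conventional "Default"/IsoData family): the threshold converges to
  the midpoint of the means of the two classes it induces.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["MomentsThreshold", "moments_threshold", "intermeans_threshold"]


@dataclass(frozen=True)
class MomentsThreshold:
    """Result of Tsai's moment-preserving threshold selection.

    Attributes
    ----------
    threshold : float
        Smallest grey level whose cumulative histogram fraction reaches
        ``p0``.  Foreground is ``image > threshold``.
    z0, z1 : float
        The two representative grey levels of the moment-preserving
        binary image (z0 < z1).
    p0 : float
        Fraction of pixels assigned to level z0 (the below-threshold
        class) before quantization at the histogram cut.
    """

    threshold: float
    z0: float
    z1: float
    p0: float


def _histogram(image: np.ndarray, nbins: int = 256):
    """Grey-level histogram: exact levels for small-range integer data,
    ``nbins`` uniform bins otherwise."""
    vals = np.asarray(image).ravel()
    if vals.size == 0:
        raise ValueError("empty image")
    if vals.dtype.kind in "ui" and np.ptp(vals) < 65536:
        lo, hi = int(vals.min()), int(vals.max())
        levels = np.arange(lo, hi + 1, dtype=float)
        counts = np.bincount((vals - lo).astype(np.int64), minlength=hi - lo + 1)
    else:
        counts, edges = np.histogram(vals, bins=nbins)
        levels = 0.5 * (edges[:-1] + edges[1:])
    return levels, counts.astype(float)


def moments_threshold(image: np.ndarray, nbins: int = 256) -> MomentsThreshold:
    """Tsai's moment-preserving threshold of a grey-level image.

    Solves for the two-level distribution sharing the image's first three
    grey-level moments, then cuts the cumulative histogram at the solved
    below-threshold fraction ``p0``.

    Raises
    ------
    ValueError
        If the image is constant (no threshold separates anything).
    """
    levels, counts = _histogram(image, nbins=nbins)
    if len(levels) < 2 or np.count_nonzero(counts) < 2:
        raise ValueError("image has fewer than two distinct grey levels")
    p = counts / counts.sum()
    m1 = float(np.dot(p, levels))
    m2 = float(np.dot(p, levels**2))
    m3 = float(np.dot(p, levels**3))

    # Representative levels z0 < z1 are the roots of z^2 + c1 z + c0 = 0.
    cd = m2 - m1 * m1
    if cd <= 0:
        raise ValueError("degenerate histogram (zero variance)")
    c0 = (m1 * m3 - m2 * m2) / cd
    c1 = (m1 * m2 - m3) / cd
    disc = c1 * c1 - 4.0 * c0
    disc = max(disc, 0.0)
    z0 = 0.5 * (-c1 - np.sqrt(disc))
    z1 = 0.5 * (-c1 + np.sqrt(disc))
    if z1 == z0:
        raise ValueError("degenerate moment solution")
    p0 = (z1 - m1) / (z1 - z0)
    p0 = float(np.clip(p0, 0.0, 1.0))

    cum = np.cumsum(p)
    idx = int(np.searchsorted(cum, p0 - 1e-12))
    idx = min(idx, len(levels) - 1)
    return MomentsThreshold(threshold=float(levels[idx]), z0=float(z0), z1=float(z1), p0=p0)


def intermeans_threshold(values: np.ndarray, tol: float = 1e-8, max_iter: int = 500) -> float:
    """Iterative intermeans threshold (two-phase region-mean fixed point).

    Starting from the middle of the intensity range, iterate ``t <-
    (mean(v <= t) + mean(v > t)) / 2`` until the threshold stops moving.
    This is the fixed point of a two-phase piecewise-constant partition
    driven by region mean intensities; the mid-range start selects the
    between-modes fixed point even when the bright phase occupies a tiny
    pixel fraction, as with sparse cells on a dark background.
    """
    v = np.asarray(values, dtype=float).ravel()
    if v.size == 0:
        raise ValueError("no values to threshold")
    lo, hi = float(v.min()), float(v.max())
    if lo == hi:
        return lo
    t = 0.5 * (lo + hi)
    for _ in range(max_iter):
        below = v[v <= t]
        above = v[v > t]
        if below.size == 0 or above.size == 0:
            break
        t_new = 0.5 * (below.mean() + above.mean())
        if abs(t_new - t) <= tol * (hi - lo):
            t = t_new
            break
        t = t_new
    return float(t)
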