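"""Windowed texture statistics: mean, variance, skewness, kurtosis.

Each statistic is computed over a sliding square window centred at every
pixel.  Edges are handled by reflection padding; nodata pixels are excluded
from each window's sample, and windows retaining fewer than 3 valid pixels
are themselves flagged nodata.

Conventions: population (biased) moment estimators; Fisher kurtosis (a
normal sample tends to 0); on a zero-variance window both skewness and
kurtosis are defined as 0.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import uniform_filter

__all__ = ["WindowStats", "compute_window_stats", "STAT_NAMES"]

STAT_NAMES = ("mean", "variance", "skewness", "kurtosis")

_MIN_VALID = 3  # fewer valid pixels than this -> window flagged nodata


@dataclass
class WindowStats:
    """Four moment planes computed over a sliding window."""

    source: str
    window: int
    mean: np.ndarray
    variance: np.ndarray
    skewness: np.ndarray
    kurtosis: np.ndarray
    nodata_mask: np.ndarray

    def plane(self, stat: str) -> np.ndarray:
        if stat not in STAT_NAMES:
            raise KeyError(f"unknown statistic {stat!r}; one of {STAT_NAMES}")
        return getattr(self, stat)


def _window_sum(plane: np.ndarray, window: int) -> np.ndarray:
    # uniform_filter with mode="reflect" == symmetric (edge-repeating) padding
    return uniform_filter(plane, size=window, mode="reflect") * (window * window)


def compute_window_stats(
    plane: np.ndarray,
    window: int,
    nodata_mask: np.ndarray | None = None,
    source: str = "",
) -> WindowStats:
    """Sliding-window mean/variance/skewness/kurtosis of one plane.

    ``window`` must be odd, >= 3 and no larger than the smaller raster
    dimension.
    """
    plane = np.asarray(plane, dtype=np.float64)
    h, w = plane.shape
    if window % 2 == 0 or window < 3 or window > min(h, w):
        raise ValueError(
            f"window must be odd, >=3 and <= min(H, W)={min(h, w)}; got {window}"
        )
    if nodata_mask is None:
        nodata_mask = np.zeros(plane.shape, dtype=bool)
    valid = (~nodata_mask).astype(np.float64)
    x = np.where(nodata_mask, 0.0, plane)

    n = _window_sum(valid, window)
    s1 = _window_sum(x * valid, window)
    s2 = _window_sum(x * x * valid, window)
    s3 = _window_sum(x ** 3 * valid, window)
    s4 = _window_sum(x ** 4 * valid, window)

    # counts are sums of 0/1 indicators; snap away float fuzz
    n = np.round(n)
    out_mask = n < _MIN_VALID
    n_safe = np.where(out_mask, 1.0, n)

    mu = s1 / n_safe
    m2 = s2 / n_safe - mu**2
    m3 = s3 / n_safe - 3.0 * mu * s2 / n_safe + 2.0 * mu**3
    m4 = s4 / n_safe - 4.0 * mu * s3 / n_safe + 6.0 * mu**2 * s2 / n_safe - 3.0 * mu**4
    m2 = np.maximum(m2, 0.0)  # guard tiny negative round-off

    degenerate = m2 <= 1e-14
    m2_safe = np.where(degenerate, 1.0, m2)
    skew = np.where(degenerate, 0.0, m3 / m2_safe**1.5)
    kurt = np.where(degenerate, 0.0, m4 / m2_safe**2 - 3.0)

    zero = np.zeros_like(mu)
    return WindowStats(
        source=source,
        window=window,
        mean=np.where(out_mask, 0.0, mu),
        variance=np.where(out_mask, zero, np.where(degenerate, 0.0, m2)),
        skewness=np.where(out_mask, 0.0, skew),
        kurtosis=np.where(out_mask, 0.0, kurt),
        nodata_mask=out_mask,
    )
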