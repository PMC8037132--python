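"""Histogram summaries with mode counting."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter1d
from scipy.signal import find_peaks
from scipy.stats import circmean, circstd

from ..errors import PepmpcError


@dataclass
class DistributionSummary:
    """Normalized histogram plus kernel-smoothed mode count."""

    bin_edges: np.ndarray
    density: np.ndarray
    mode_count: int
    mean: float
    spread: float
    circular: bool = False


def distribution(series, n_bins: int = 50, circular: bool = False,
                 smooth_bins: float = 2.0,
                 prominence_fraction: float = 0.10) -> DistributionSummary:
    """Summarize a scalar series as a normalized histogram.

    Modes are local maxima of the Gaussian-smoothed density whose peak
    prominence exceeds ``prominence_fraction`` of the density maximum.
    Circular series (angles in radians) are histogrammed over (-pi, pi]
    with wrapped smoothing and circular mean/spread.
    """
    series = np.asarray(series, float)
    series = series[np.isfinite(series)]
    if series.size == 0:
        raise PepmpcError("empty series")
    if n_bins < 2:
        raise PepmpcError("need at least 2 bins")
    if circular:
        edges = np.linspace(-np.pi, np.pi, n_bins + 1)
        wrapped = np.arctan2(np.sin(series), np.cos(series))
        density, edges = np.histogram(wrapped, bins=edges, density=True)
        smoothed = gaussian_filter1d(density, smooth_bins, mode="wrap")
        mean = float(circmean(series, high=np.pi, low=-np.pi))
        spread = float(circstd(series, high=np.pi, low=-np.pi))
        # pad circularly so peaks at the boundary are found
        padded = np.concatenate([smoothed[-n_bins // 4:], smoothed,
                                 smoothed[:n_bins // 4]])
        pad = n_bins // 4
        peaks, _ = find_peaks(
            padded, prominence=prominence_fraction * smoothed.max())
        peaks = np.unique((peaks - pad) % n_bins)
        peaks = peaks[(peaks >= 0) & (peaks < n_bins)]
        mode_count = max(1, len(peaks))
    else:
        density, edges = np.histogram(series, bins=n_bins, density=True)
        smoothed = gaussian_filter1d(density, smooth_bins, mode="nearest")
        mean = float(series.mean())
        spread = float(series.std())
        interior, _ = find_peaks(
            smoothed, prominence=prominence_fraction * smoothed.max())
        mode_count = len(interior)
        # boundary bins can hold a mode that find_peaks misses
        if smoothed[0] > smoothed[1] and \
                smoothed[0] >= prominence_fraction * smoothed.max():
            mode_count += 1
        if smoothed[-1] > smoothed[-2] and \
                smoothed[-1] >= prominence_fraction * smoothed.max():
            mode_count += 1
        mode_count = max(1, mode_count)
    return DistributionSummary(bin_edges=edges, density=density,
                               mode_count=int(mode_count), mean=mean,
                               spread=spread, circular=circular)
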