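"""Breath detection, respiration-rate computation and evaluation metrics.

The "advanced counting" breath detector finds local maxima of the detrended
respiration signal and discards breaths whose peak-to-trough excursion is
small relative to the window's typical excursion, which suppresses spurious
ripples from noise.  Instantaneous rates come from successive breath-peak
intervals; the average rate uses the span between the first and last peak.

The distance transform maps a set of breath-peak locations to a per-sample
distance-to-nearest-peak series whose minima coincide exactly with the
peaks; the mean absolute error between two such transforms (DT-MAE) scores
how well two waveforms agree on breath locations without requiring a
peak-to-peak pairing.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage, signal

__all__ = ["BreathSet", "advanced_count_rr", "distance_transform", "dt_mae",
           "mae", "rmse"]


@dataclass
class BreathSet:
    """Detected breath peaks with derived instantaneous and average rates."""

    peak_indices: np.ndarray          # sorted sample indices
    fs: float                         # Hz
    rr_inst: np.ndarray = field(default_factory=lambda: np.empty(0))  # BrPM
    rr_avg: float = float("nan")      # BrPM; NaN when undefined
    rr_avg_defined: bool = False

    def __post_init__(self):
        self.peak_indices = np.asarray(self.peak_indices, dtype=np.intp)
        if np.any(np.diff(self.peak_indices) <= 0):
            raise ValueError("peak indices must be strictly increasing")


def _local_maxima(x: np.ndarray) -> np.ndarray:
    """Interior local maxima; on flat-topped plateaus the earliest index wins."""
    n = len(x)
    if n < 3:
        return np.empty(0, dtype=np.intp)
    idx = np.nonzero((x[1:-1] > x[:-2]) & (x[1:-1] >= x[2:]))[0] + 1
    return idx.astype(np.intp)


def advanced_count_rr(resp, fs: float, *, excursion_frac: float = 0.2,
                      excursion_percentile: float = 75.0) -> BreathSet:
    """Count breathing peaks with amplitude-based rejection of small ripples.

    Parameters
    ----------
    resp : array
        Respiration series (any amplitude scale; the detector is invariant
        to positive rescaling).
    fs : float
        Sampling rate in Hz.
    excursion_frac, excursion_percentile : float
        A peak survives if its peak-to-trough excursion exceeds
        ``excursion_frac`` times the ``excursion_percentile``-th percentile
        of all candidate excursions in the window.

    Returns
    -------
    BreathSet
        With ``rr_avg_defined=False`` (and NaN average) when fewer than two
        peaks survive; never raises for peak-free input.
    """
    x = np.asarray(resp, dtype=np.float64)
    if x.ndim != 1:
        raise ValueError("resp must be one-dimensional")
    if len(x) < 2 * fs:
        raise ValueError("need at least 2 s of signal")
    x = signal.detrend(x, type="linear")
    cand = _local_maxima(x)
    if len(cand) == 0:
        return BreathSet(np.empty(0, dtype=np.intp), fs)
    # peak-to-trough excursion: the shallower of the drops to the deepest
    # sample on either side (bounded by the neighbouring candidate peaks)
    bounds = np.concatenate(([0], cand, [len(x) - 1]))
    exc = np.empty(len(cand))
    for k, p in enumerate(cand):
        left_min = x[bounds[k]:p + 1].min()
        right_min = x[p:bounds[k + 2] + 1].min()
        exc[k] = x[p] - max(left_min, right_min)
    thresh = excursion_frac * np.percentile(exc, excursion_percentile)
    peaks = cand[exc >= thresh]
    if len(peaks) < 2:
        return BreathSet(peaks, fs)
    d = np.diff(peaks)
    rr_inst = 60.0 * fs / d
    rr_avg = 60.0 * (len(peaks) - 1) * fs / (peaks[-1] - peaks[0])
    return BreathSet(peaks, fs, rr_inst=rr_inst, rr_avg=float(rr_avg),
                     rr_avg_defined=True)


def distance_transform(peak_indices, length: int) -> np.ndarray:
    """Distance to the nearest peak: out[i] = min_p |i - p|.

    Zero exactly at the peaks; 1-Lipschitz everywhere.
    """
    peaks = np.asarray(peak_indices, dtype=np.intp)
    if length < 1:
        raise ValueError("length must be >= 1")
    if peaks.size == 0:
        raise ValueError("distance transform undefined for an empty peak set")
    if peaks.min() < 0 or peaks.max() >= length:
        raise ValueError("peak indices must lie within [0, length)")
    mask = np.ones(length, dtype=bool)
    mask[peaks] = False
    return ndimage.distance_transform_edt(mask)


def dt_mae(dt_a, dt_b) -> float:
    """Mean absolute difference of two distance transforms (symmetric, >= 0)."""
    a = np.asarray(dt_a, dtype=np.float64)
    b = np.asarray(dt_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError(f"length mismatch: {a.shape} vs {b.shape}")
    return float(np.mean(np.abs(a - b)))


def mae(a, b) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size or a.size == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    return float(np.mean(np.abs(a - b)))


def rmse(a, b) -> float:
    a = np.asarray(a, dtype=np.float64).ravel()
    b = np.asarray(b, dtype=np.float64).ravel()
    if a.size != b.size or a.size == 0:
        raise ValueError("inputs must be non-empty and of equal length")
    return float(np.sqrt(np.mean((a - b) ** 2)))
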