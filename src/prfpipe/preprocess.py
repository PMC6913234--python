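"""Time-series conditioning before pRF fitting.

Order of operations mirrors the mapping analysis: each run is linearly
detrended and z-standardized per vertex, runs are averaged, and the averaged
series may then be low-pass filtered with a temporal Gaussian kernel
(standard deviation 1 or 2 s) to emulate slower acquisitions.  Only the
data are filtered, never the model prediction: the size bias under study
arises precisely because the filter blurs responses to temporally adjacent
bar positions while the predictor stays sharp.

Degenerate vertices (zero residual variance) propagate as NaN columns and
are excluded from fitting rather than silently zeroed.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter1d

__all__ = [
    "TimeSeriesSet",
    "detrend_zscore",
    "average_runs",
    "gaussian_lowpass",
    "preprocess_runs",
]


@dataclass
class TimeSeriesSet:
    """BOLD matrix of shape (runs, time, vertices) with TR metadata."""

    data: np.ndarray
    tr_s: float
    run_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=np.float64)
        if self.data.ndim != 3:
            raise ValueError("data must be (runs, time, vertices)")
        if not self.tr_s > 0:
            raise ValueError("tr_s must be positive")
        if not self.run_ids:
            self.run_ids = [f"run{i + 1}" for i in range(self.data.shape[0])]
        if len(self.run_ids) != self.data.shape[0]:
            raise ValueError("run_ids length must match run count")

    @property
    def n_runs(self) -> int:
        return int(self.data.shape[0])

    @property
    def n_frames(self) -> int:
        return int(self.data.shape[1])

    @property
    def n_vertices(self) -> int:
        return int(self.data.shape[2])


def detrend_zscore(series: np.ndarray, axis: int = 0) -> np.ndarray:
    """Remove the least-squares line, then standardize to mean 0 / SD 1.

    Works on a vector or along ``axis`` of a matrix.  A series that is an
    exact line has zero residual variance; it comes back as NaN (the
    degenerate flag) rather than raising.
    """
    x = np.asarray(series, dtype=np.float64)
    n = x.shape[axis]
    if n < 3:
        raise ValueError("need at least 3 time points to detrend")
    t = np.arange(n) - (n - 1) / 2.0  # centred regressor: slope and mean decouple
    shape = [1] * x.ndim
    shape[axis] = n
    tb = t.reshape(shape)
    slope = (x * tb).sum(axis=axis, keepdims=True) / (t * t).sum()
    resid = x - x.mean(axis=axis, keepdims=True) - slope * tb
    sd = resid.std(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = resid / sd
    return np.where(sd == 0, np.nan, out) if np.any(sd == 0) else out


def average_runs(tss: TimeSeriesSet) -> np.ndarray:
    """Arithmetic mean over runs → (time, vertices).

    Expects runs already detrended and z-scored; NaN (degenerate) vertices
    propagate into the average.
    """
    if tss.n_runs == 1:
        warnings.warn("averaging a single run is the identity", stacklevel=2)
    return tss.data.mean(axis=0)


def gaussian_lowpass(
    series: np.ndarray, kernel_sd_s: float, tr_s: float, axis: int = 0
) -> np.ndarray:
    """Convolve with a discrete temporal Gaussian (SD in seconds).

    The kernel is truncated at ±3 SD and renormalised to unit sum, so a
    constant series passes through unchanged; edges use reflection padding
    to avoid endpoint attenuation on finite scans.
    """
    if not kernel_sd_s > 0:
        raise ValueError("kernel_sd_s must be positive")
    if not tr_s > 0:
        raise ValueError("tr_s must be positive")
    x = np.asarray(series, dtype=np.float64)
    return gaussian_filter1d(
        x, sigma=kernel_sd_s / tr_s, axis=axis, mode="reflect", truncate=3.0
    )


def preprocess_runs(
    tss: TimeSeriesSet, filter_sd_s: float | None = None
) -> np.ndarray:
    """Full conditioning chain: per-run detrend + z-score → average → filter.

    Returns the (time, vertices) matrix ready for fitting; ``filter_sd_s``
    of None skips the low-pass stage.
    """
    conditioned = detrend_zscore(tss.data, axis=1)
    mean = TimeSeriesSet(conditioned, tss.tr_s, list(tss.run_ids))
    avg = average_runs(mean)
    if filter_sd_s is not None:
        avg = gaussian_lowpass(avg, filter_sd_s, tss.tr_s, axis=0)
    return avg
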