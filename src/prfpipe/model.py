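"""Gaussian pRF forward model: profile × aperture overlap, HRF convolution.

A population receptive field is modelled as an isotropic two-dimensional
Gaussian in visual-field coordinates, parameterised by its centre (x0, y0)
in degrees and standard deviation σ (the pRF size).  The predicted neural
response at each frame is the overlap of the binary stimulus aperture with
the Gaussian profile — each frame of the mask multiplied by the profile and
summed over pixels.  The neural time course is convolved with a canonical
double-gamma haemodynamic response function and z-standardized; because the
fit criterion is a correlation, the prediction carries no meaningful gain
and the model is scale-invariant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats as _stats

from .design import ApertureMovie

__all__ = [
    "PRFParams",
    "HRFSpec",
    "prf_profile",
    "neural_response",
    "hrf_kernel",
    "convolve_hrf",
    "zscore",
    "predict_timeseries",
]


@dataclass(frozen=True)
class PRFParams:
    """Centre (degrees of visual angle) and size σ (degrees) of one pRF."""

    x0: float
    y0: float
    sigma: float

    def __post_init__(self) -> None:
        if not self.sigma > 0:
            raise ValueError(f"sigma must be positive, got {self.sigma}")
        if not np.isfinite([self.x0, self.y0, self.sigma]).all():
            raise ValueError("pRF parameters must be finite")

    @property
    def eccentricity(self) -> float:
        return float(np.hypot(self.x0, self.y0))

    @property
    def polar_angle(self) -> float:
        """Polar angle in radians, counter-clockwise from the +x axis."""
        return float(np.arctan2(self.y0, self.x0))


@dataclass(frozen=True)
class HRFSpec:
    """Double-gamma haemodynamic response function parameters.

    Defaults are the widely used canonical shape: response peak near 5–6 s,
    undershoot near 16 s, undershoot amplitude 1/6 of the peak.  ``duration_s``
    of 40 s covers the kernel mass to well below 1e-4 of the peak.
    """

    peak_delay_s: float = 6.0
    undershoot_delay_s: float = 16.0
    peak_dispersion: float = 1.0
    undershoot_dispersion: float = 1.0
    peak_undershoot_ratio: float = 6.0
    duration_s: float = 40.0
    dt_s: float = 1.0

    def __post_init__(self) -> None:
        for name in (
            "peak_delay_s",
            "undershoot_delay_s",
            "peak_dispersion",
            "undershoot_dispersion",
            "peak_undershoot_ratio",
            "duration_s",
            "dt_s",
        ):
            if not getattr(self, name) > 0:
                raise ValueError(f"{name} must be positive")


def hrf_kernel(spec: HRFSpec = HRFSpec()) -> np.ndarray:
    """Sample the double-gamma HRF at ``dt_s`` and scale its peak to 1.

    Causal: the kernel starts at t = 0 where both gamma densities vanish.
    """
    t = np.arange(0.0, spec.duration_s + spec.dt_s / 2.0, spec.dt_s)
    peak = _stats.gamma.pdf(
        t, a=spec.peak_delay_s / spec.peak_dispersion, scale=spec.peak_dispersion
    )
    under = _stats.gamma.pdf(
        t,
        a=spec.undershoot_delay_s / spec.undershoot_dispersion,
        scale=spec.undershoot_dispersion,
    )
    kernel = peak - under / spec.peak_undershoot_ratio
    return kernel / kernel.max()


def prf_profile(
    params: PRFParams, X: np.ndarray, Y: np.ndarray
) -> np.ndarray:
    """Unnormalised Gaussian sensitivity profile over pixel centres (X, Y).

    weight(pixel) = exp(−((px−x0)² + (py−y0)²) / (2σ²)); the peak value is 1
    when the centre falls on a pixel centre.
    """
    if X.shape != Y.shape:
        raise ValueError("X and Y grids must share a shape")
    return np.exp(
        -((X - params.x0) ** 2 + (Y - params.y0) ** 2) / (2.0 * params.sigma**2)
    )


def neural_response(profile: np.ndarray, movie: ApertureMovie) -> np.ndarray:
    """Overlap of each aperture frame with a pRF profile.

    response[t] = Σ_pixels mask[t] · weight — nonnegative, exactly zero on
    baseline frames.
    """
    if profile.shape != movie.frames.shape[1:]:
        raise ValueError(
            f"profile shape {profile.shape} does not match movie geometry "
            f"{movie.frames.shape[1:]}"
        )
    return movie.flat_frames() @ profile.ravel()


def convolve_hrf(neural: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Zero-padded causal convolution, truncated to the input length.

    Accepts a vector (n_frames,) or matrix (n_frames, n_series); columns are
    convolved independently with the same kernel.
    """
    if neural.ndim == 1:
        return np.convolve(neural, kernel)[: neural.shape[0]]
    out = np.empty_like(neural, dtype=np.float64)
    for j in range(neural.shape[1]):
        out[:, j] = np.convolve(neural[:, j], kernel)[: neural.shape[0]]
    return out


def zscore(x: np.ndarray, axis: int = 0) -> np.ndarray:
    """Standardize to mean 0 / SD 1 along ``axis``; zero-variance → NaN.

    NaN columns act as the degenerate flag throughout the pipeline; they are
    skipped by the fitter rather than raising.
    """
    x = np.asarray(x, dtype=np.float64)
    mu = x.mean(axis=axis, keepdims=True)
    sd = x.std(axis=axis, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = (x - mu) / sd
    if np.ndim(sd) and (sd == 0).any():
        out = np.where(sd == 0, np.nan, out)
    return out


def predict_timeseries(
    params: PRFParams, movie: ApertureMovie, hrf: HRFSpec = HRFSpec()
) -> np.ndarray | None:
    """Z-scored predicted BOLD series for one pRF, or None when degenerate.

    The movie must exclude dummy frames.  A pRF with no effective stimulus
    overlap produces a constant response whose z-score is undefined; such
    predictions are flagged by returning None so the grid search can skip
    them silently.
    """
    X, Y = movie.pixel_grid()
    neural = neural_response(prf_profile(params, X, Y), movie)
    # overlap below ~1e-12 of a single pixel's weight is numerically noise,
    # not signal: a pRF that far outside the aperture is degenerate
    if neural.max() < 1e-12:
        return None
    bold = convolve_hrf(neural, hrf_kernel(hrf))
    sd = bold.std()
    if sd == 0 or not np.isfinite(sd):
        return None
    return (bold - bold.mean()) / sd
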