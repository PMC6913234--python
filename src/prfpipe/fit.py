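"""Two-stage pRF estimation: grid-search coarse fit, simplex fine fit, betas.

The coarse stage correlates each vertex's observed series against a
precomputed grid of candidate predictions (by default 30 polar angles × 17
eccentricities × 15 sigmas = 7,650 candidates).  The best candidate seeds a
derivative-free Nelder–Mead refinement of (x0, y0, σ) maximising the Pearson
correlation, provided the coarse R² exceeds a 0.01 gate.  Amplitude β1 and
baseline β0 are then obtained by ordinary least squares of the observed
series on the final prediction.  R² throughout is the squared Pearson
correlation between observed and predicted series.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .design import ApertureMovie
from .model import (
    HRFSpec,
    PRFParams,
    convolve_hrf,
    hrf_kernel,
    neural_response,
    prf_profile,
)

__all__ = [
    "GridSpec",
    "SearchGrid",
    "FitConfig",
    "CoarseFit",
    "FineFit",
    "build_grid",
    "coarse_fit",
    "fine_fit",
    "fit_betas",
    "fit_vertex",
    "fit_map",
]

logger = logging.getLogger(__name__)

#: R² thresholds used at distinct stages of the analysis.
R2_GATE = 0.01  # coarse fit must exceed this to enter the fine fit
R2_DISPLAY = 0.10  # map display / map comparison threshold
R2_SUMMARY = 0.15  # inclusion threshold for pRF-size and CMF summaries


@dataclass(frozen=True)
class GridSpec:
    """Axes of the coarse search grid (polar angle × eccentricity × σ).

    The default factorisation 30 × 17 × 15 yields 7,650 candidates: polar
    angles evenly spaced over the full circle, eccentricities and sigmas
    log-spaced over the plausible range for a 19° aperture.
    """

    n_angles: int = 30
    n_eccentricities: int = 17
    ecc_range: tuple[float, float] = (0.25, 9.5)
    n_sigmas: int = 15
    sigma_range: tuple[float, float] = (0.1, 5.0)

    def __post_init__(self) -> None:
        if min(self.n_angles, self.n_eccentricities, self.n_sigmas) < 1:
            raise ValueError("every grid axis needs at least one value")
        if self.ecc_range[0] < 0 or self.ecc_range[0] > self.ecc_range[1]:
            raise ValueError("bad eccentricity range")
        if self.sigma_range[0] <= 0 or self.sigma_range[0] > self.sigma_range[1]:
            raise ValueError("bad sigma range")

    @property
    def n_candidates(self) -> int:
        return self.n_angles * self.n_eccentricities * self.n_sigmas

    def axes(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        angles = np.arange(self.n_angles) * (2 * np.pi / self.n_angles)
        if self.n_eccentricities == 1:
            eccs = np.array([self.ecc_range[0]])
        else:
            eccs = np.geomspace(*self.ecc_range, self.n_eccentricities)
        if self.n_sigmas == 1:
            sigmas = np.array([self.sigma_range[0]])
        else:
            sigmas = np.geomspace(*self.sigma_range, self.n_sigmas)
        return angles, eccs, sigmas


@dataclass
class SearchGrid:
    """Precomputed candidate parameters and z-scored predictions.

    ``predictions`` is (n_frames, n_candidates); degenerate candidates carry
    NaN columns and True in ``degenerate`` and are skipped by the search.
    Candidate order is angle-major, then eccentricity, then σ — ties at
    equal correlation resolve to the first candidate in this order.
    """

    params: np.ndarray  # (n_candidates, 3) columns x0, y0, sigma
    predictions: np.ndarray  # (n_frames, n_candidates), z-scored columns
    degenerate: np.ndarray  # (n_candidates,) bool
    spec: GridSpec

    @property
    def n_candidates(self) -> int:
        return int(self.params.shape[0])


def build_grid(
    spec: GridSpec, movie: ApertureMovie, hrf: HRFSpec = HRFSpec()
) -> SearchGrid:
    """Materialise the coarse search grid for one aperture movie.

    Candidates whose eccentricity exceeds the aperture radius by more than
    2σ, or whose prediction has no variance, are flagged degenerate.
    """
    angles, eccs, sigmas = spec.axes()
    A, E, S = np.meshgrid(angles, eccs, sigmas, indexing="ij")
    x0 = (E * np.cos(A)).ravel()
    y0 = (E * np.sin(A)).ravel()
    sg = S.ravel()
    params = np.column_stack([x0, y0, sg])

    X, Y = movie.pixel_grid()
    px = X.ravel()
    py = Y.ravel()
    frames = movie.flat_frames()
    n_c = params.shape[0]
    kernel = hrf_kernel(hrf)

    predictions = np.full((movie.n_frames, n_c), np.nan)
    degenerate = np.zeros(n_c, dtype=bool)
    radius = movie.aperture_radius_deg

    chunk = 512  # bounds the (n_pixels × chunk) profile block
    for lo in range(0, n_c, chunk):
        hi = min(lo + chunk, n_c)
        d2 = (px[:, None] - x0[lo:hi]) ** 2 + (py[:, None] - y0[lo:hi]) ** 2
        profiles = np.exp(-d2 / (2.0 * sg[lo:hi] ** 2))
        neural = frames @ profiles
        bold = convolve_hrf(neural, kernel)
        mu = bold.mean(axis=0)
        sd = bold.std(axis=0)
        ecc = np.hypot(x0[lo:hi], y0[lo:hi])
        bad = (sd == 0) | (ecc > radius + 2.0 * sg[lo:hi])
        with np.errstate(divide="ignore", invalid="ignore"):
            z = (bold - mu) / sd
        z[:, bad] = np.nan
        predictions[:, lo:hi] = z
        degenerate[lo:hi] = bad

    logger.info(
        "built search grid: %d candidates (%d degenerate)", n_c, degenerate.sum()
    )
    return SearchGrid(params=params, predictions=predictions, degenerate=degenerate, spec=spec)


@dataclass(frozen=True)
class CoarseFit:
    params: PRFParams | None
    r_squared: float
    passed_gate: bool


@dataclass(frozen=True)
class FineFit:
    params: PRFParams
    r_squared: float
    stage: str  # "fine" or "coarse-only"


@dataclass(frozen=True)
class FitConfig:
    """Knobs of the per-vertex fitting chain."""

    gate_r2: float = R2_GATE
    do_fine: bool = True
    fine_xatol: float = 1e-2
    fine_fatol: float = 1e-6
    fine_maxfev: int = 400


def _zscore_1d(x: np.ndarray) -> np.ndarray | None:
    sd = x.std()
    if sd == 0 or not np.isfinite(sd):
        return None
    return (x - x.mean()) / sd


def coarse_fit(observed: np.ndarray, grid: SearchGrid, gate_r2: float = R2_GATE) -> CoarseFit:
    """Exhaustive grid search: argmax of Pearson r over candidates.

    Returns a below-threshold marker (``passed_gate`` False, params still
    reported when defined) when the best R² does not exceed the gate, and a
    failed marker (params None) for degenerate observed series.
    """
    obs = np.asarray(observed, dtype=np.float64)
    if obs.shape[0] != grid.predictions.shape[0]:
        raise ValueError("observed length does not match grid predictions")
    if not np.isfinite(obs).all():
        return CoarseFit(None, np.nan, False)
    obs_z = _zscore_1d(obs)
    if obs_z is None:
        return CoarseFit(None, np.nan, False)
    n = obs.shape[0]
    r = obs_z @ grid.predictions / n  # z·z/n is exactly Pearson r
    r = np.where(np.isnan(r), -np.inf, r)
    r2 = r**2
    # signed maximum: a pRF drives a positive response, so anti-correlated
    # candidates are not acceptable fits
    best = int(np.argmax(r))
    if not np.isfinite(r[best]):
        return CoarseFit(None, np.nan, False)
    x0, y0, sg = grid.params[best]
    return CoarseFit(
        PRFParams(float(x0), float(y0), float(sg)),
        float(r2[best]),
        bool(r2[best] > gate_r2),
    )


def _pearson_objective(
    observed_z: np.ndarray,
    movie: ApertureMovie,
    kernel: np.ndarray,
    X: np.ndarray,
    Y: np.ndarray,
):
    frames = movie.flat_frames()
    n = observed_z.shape[0]

    def negative_r(u: np.ndarray) -> float:
        x0, y0, log_sigma = u
        sigma = float(np.exp(log_sigma))
        w = np.exp(-((X - x0) ** 2 + (Y - y0) ** 2) / (2.0 * sigma**2))
        neural = frames @ w.ravel()
        bold = np.convolve(neural, kernel)[:n]
        sd = bold.std()
        if sd == 0 or not np.isfinite(sd):
            return 1.0  # worse than any achievable correlation
        r = float(observed_z @ ((bold - bold.mean()) / sd) / n)
        return -r

    return negative_r


def fine_fit(
    observed: np.ndarray,
    init: PRFParams,
    movie: ApertureMovie,
    hrf: HRFSpec = HRFSpec(),
    config: FitConfig = FitConfig(),
) -> FineFit:
    """Nelder–Mead refinement of (x0, y0, σ) maximising Pearson r.

    σ stays positive through a log reparameterisation.  If the optimiser
    fails or ends below the initial correlation, the coarse parameters are
    returned with stage "coarse-only".
    """
    obs_z = _zscore_1d(np.asarray(observed, dtype=np.float64))
    if obs_z is None:
        raise ValueError("observed series has no variance")
    X, Y = movie.pixel_grid()
    objective = _pearson_objective(obs_z, movie, hrf_kernel(hrf), X, Y)
    u0 = np.array([init.x0, init.y0, np.log(init.sigma)])
    r_init = -objective(u0)
    try:
        res = minimize(
            objective,
            u0,
            method="Nelder-Mead",
            options={
                "xatol": config.fine_xatol,
                "fatol": config.fine_fatol,
                "maxfev": config.fine_maxfev,
            },
        )
    except Exception:  # pragma: no cover - optimiser crash is a fallback path
        return FineFit(init, float(max(r_init, 0.0) ** 2), "coarse-only")
    r_fine = -res.fun
    if not np.isfinite(r_fine) or r_fine < r_init - 1e-12:
        return FineFit(init, float(r_init**2), "coarse-only")
    x0, y0, log_sigma = res.x
    return FineFit(
        PRFParams(float(x0), float(y0), float(np.exp(log_sigma))),
        float(r_fine**2),
        "fine",
    )


def fit_betas(observed_raw: np.ndarray, prediction: np.ndarray) -> tuple[float, float]:
    """OLS of the observed series on the (z-scored) prediction.

    Returns (beta1, beta0): response amplitude and baseline intercept.
    """
    obs = np.asarray(observed_raw, dtype=np.float64)
    pred = np.asarray(prediction, dtype=np.float64)
    if obs.shape != pred.shape:
        raise ValueError("observed and prediction must share a length")
    design = np.column_stack([pred, np.ones_like(pred)])
    coef, *_ = np.linalg.lstsq(design, obs, rcond=None)
    return float(coef[0]), float(coef[1])


def fit_vertex(
    observed: np.ndarray,
    grid: SearchGrid,
    movie: ApertureMovie,
    hrf: HRFSpec = HRFSpec(),
    config: FitConfig = FitConfig(),
) -> dict:
    """Coarse → gate → fine → betas for one vertex; returns a result record."""
    record = {
        "x0": np.nan,
        "y0": np.nan,
        "sigma": np.nan,
        "beta1": np.nan,
        "beta0": np.nan,
        "r2": np.nan,
        "stage": "failed",
    }
    coarse = coarse_fit(observed, grid, gate_r2=config.gate_r2)
    if coarse.params is None:
        return record
    if not coarse.passed_gate:
        record.update(
            x0=coarse.params.x0,
            y0=coarse.params.y0,
            sigma=coarse.params.sigma,
            r2=coarse.r_squared,
            stage="failed",
        )
        return record
    if config.do_fine:
        fine = fine_fit(observed, coarse.params, movie, hrf, config)
    else:
        fine = FineFit(coarse.params, coarse.r_squared, "coarse-only")
    from .model import predict_timeseries

    pred = predict_timeseries(fine.params, movie, hrf)
    if pred is None:  # refined pRF drifted outside the stimulated region
        pred = predict_timeseries(coarse.params, movie, hrf)
        fine = FineFit(coarse.params, coarse.r_squared, "coarse-only")
    beta1, beta0 = fit_betas(observed, pred)
    record.update(
        x0=fine.params.x0,
        y0=fine.params.y0,
        sigma=fine.params.sigma,
        beta1=beta1,
        beta0=beta0,
        r2=fine.r_squared,
        stage=fine.stage,
    )
    return record


def fit_map(
    data: np.ndarray,
    grid: SearchGrid,
    movie: ApertureMovie,
    hrf: HRFSpec = HRFSpec(),
    config: FitConfig = FitConfig(),
    vertex_ids: np.ndarray | None = None,
) -> pd.DataFrame:
    """Fit every column of a (time, vertices) matrix.

    Deterministic given identical inputs; one output row per vertex with
    columns vertex_id, x0, y0, sigma, beta1, beta0, r2, stage.
    """
    data = np.asarray(data, dtype=np.float64)
    if data.ndim != 2:
        raise ValueError("data must be (time, vertices)")
    n_v = data.shape[1]
    if vertex_ids is None:
        vertex_ids = np.arange(n_v)
    rows = []
    for v in range(n_v):
        rec = fit_vertex(data[:, v], grid, movie, hrf, config)
        rec["vertex_id"] = vertex_ids[v]
        rows.append(rec)
        if (v + 1) % 100 == 0:
            logger.info("fitted %d / %d vertices", v + 1, n_v)
    cols = ["vertex_id", "x0", "y0", "sigma", "beta1", "beta0", "r2", "stage"]
    return pd.DataFrame(rows)[cols]
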