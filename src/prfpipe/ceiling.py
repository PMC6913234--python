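"""Split-half reliability and the noise ceiling on goodness-of-fit.

The mapping runs are split into even- and odd-numbered halves, each half is
averaged, and the Pearson correlation r′ between the two half-averages per
vertex is stepped up to the reliability of the full six-run average with
the Spearman–Brown prophecy formula, r_obs = 2r′ / (1 + r′).  Assuming a
perfectly reliable predictor and a true model (ρ_h = r_pred = 1), the
maximum observable squared correlation — the noise ceiling ρ_o² — equals
r_obs.  Dividing a vertex's fitted R² by its ceiling gives a
reliability-normalised goodness-of-fit comparable across datasets with
different noise levels.

Negative split-half correlations leave the ceiling undefined (NaN flag)
rather than being clamped to zero; callers can count the flags.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .preprocess import TimeSeriesSet, detrend_zscore

__all__ = [
    "split_half_r",
    "spearman_brown",
    "noise_ceiling_map",
    "normalized_fit",
]


def _pearson_columns(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Column-wise Pearson correlation of two (time, vertices) matrices."""
    a = a - a.mean(axis=0, keepdims=True)
    b = b - b.mean(axis=0, keepdims=True)
    denom = np.sqrt((a * a).sum(axis=0) * (b * b).sum(axis=0))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = (a * b).sum(axis=0) / denom
    return np.where(denom == 0, np.nan, r)


def split_half_r(tss: TimeSeriesSet, preprocess: bool = True) -> np.ndarray:
    """Per-vertex Pearson r between even-run and odd-run averages.

    Runs are split by order index (runs 1,3,5 vs 2,4,6).  With
    ``preprocess`` True each run is detrended and z-scored first, matching
    the conditioning applied before fitting.  Degenerate vertices → NaN.
    """
    if tss.n_runs < 2:
        raise ValueError("split-half reliability needs at least 2 runs")
    data = detrend_zscore(tss.data, axis=1) if preprocess else tss.data
    odd = data[0::2].mean(axis=0)  # runs 1, 3, 5 (1-based)
    even = data[1::2].mean(axis=0)  # runs 2, 4, 6
    return _pearson_columns(odd, even)


def spearman_brown(r_split: np.ndarray | float) -> np.ndarray | float:
    """Step up a half-data correlation to full-data reliability: 2r/(1+r).

    Strictly increasing on (−1, 1] and mapping [0, 1] onto [0, 1]; r = −1 is
    undefined (NaN).
    """
    r = np.asarray(r_split, dtype=np.float64)
    if np.any(np.abs(r[np.isfinite(r)]) > 1):
        raise ValueError("correlations must lie in [-1, 1]")
    with np.errstate(divide="ignore", invalid="ignore"):
        out = 2.0 * r / (1.0 + r)
    out = np.where(r == -1.0, np.nan, out)
    return float(out) if np.isscalar(r_split) else out


def noise_ceiling_map(tss: TimeSeriesSet, preprocess: bool = True) -> pd.DataFrame:
    """Per-vertex reliability table: r_split, r_obs, and the ceiling ρ_o².

    ceiling = r_obs where r_obs > 0, NaN (undefined) otherwise.
    """
    r_split = split_half_r(tss, preprocess=preprocess)
    r_obs = spearman_brown(r_split)
    with np.errstate(invalid="ignore"):
        ceiling = np.where(r_obs > 0, r_obs, np.nan)
    return pd.DataFrame(
        {
            "vertex_id": np.arange(tss.n_vertices),
            "r_split": r_split,
            "r_obs": r_obs,
            "ceiling": ceiling,
        }
    )


def normalized_fit(
    r_squared: np.ndarray | float, ceiling: np.ndarray | float
) -> np.ndarray | float:
    """Noise-ceiling-normalised goodness-of-fit: R² / ρ_o².

    May exceed 1 under sampling noise; values are not clipped.  An undefined
    ceiling propagates as NaN.
    """
    r2 = np.asarray(r_squared, dtype=np.float64)
    c = np.asarray(ceiling, dtype=np.float64)
    with np.errstate(divide="ignore", invalid="ignore"):
        out = r2 / c
    out = np.where(c == 0, np.nan, out)
    n_extreme = int(np.sum(out[np.isfinite(out)] > 1.5))
    if n_extreme:
        import warnings

        warnings.warn(
            f"{n_extreme} normalised fits exceed 1.5 (unreliable ceiling?)",
            stacklevel=2,
        )
    scalar = np.isscalar(r_squared) and np.isscalar(ceiling)
    return float(out) if scalar else out
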