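"""Simulate noisy mapping runs and recover pRF parameters.

Ground-truth pRFs follow the size law σ = 0.3 + 0.34·eccentricity; six
250-frame runs at TR = 1 s get white noise calibrated so the fitted R² of
the run average sits near 0.3, the regime of fast-TR acquisitions.
"""

import numpy as np

from prfpipe import BarDesign, GridSpec, HRFSpec, build_grid, fit_map, generate_apertures
from prfpipe.preprocess import preprocess_runs
from prfpipe.simulate import DriftSpec, make_truth_layout, simulate_runs

movie = generate_apertures(BarDesign(mask_resolution_px=50), include_dummies=False)
hrf = HRFSpec()
grid = build_grid(GridSpec(), movie, hrf)  # 7,650 candidates

truth = make_truth_layout(
    40, ecc_range=(0.5, 8.0), sigma_law=(0.3, 0.3375), noise_sd=3.7,
    drift=DriftSpec(0.0, 0.0), seed=1,
)
dataset = simulate_runs(truth, movie, hrf)
data = preprocess_runs(dataset.runs)  # detrend → z-score → average
fits = fit_map(data, grid, movie, hrf)

t = truth.table
rel_sigma = np.abs(fits["sigma"] - t["sigma"]) / t["sigma"]
pos_err = np.hypot(fits["x0"] - t["x0"], fits["y0"] - t["y0"])
print(fits.head(5).to_string(index=False))
print(f"\nmean fitted R²:             {fits['r2'].mean():.3f}")
print(f"median sigma error:         {100 * np.median(rel_sigma):.1f}%")
print(f"median position error:      {np.median(pos_err):.2f} deg")

# At this noise level the correlation surface over σ is shallow for small
# pRFs, so per-vertex size estimates scatter widely even though position
# and the σ-vs-eccentricity trend remain usable.
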