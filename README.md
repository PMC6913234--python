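# prfpipe

Population receptive field (pRF) mapping analysis for fMRI retinotopy, as a
tested, desk-scale Python pipeline: sweeping-bar stimulus apertures, a
Gaussian pRF forward model, two-stage model fitting, temporal low-pass
filtering, split-half noise ceilings, cortical magnification on surface
patches, eccentricity-binned summaries — plus a synthetic-data generator so
every stage can be exercised and validated without scanner data.

It is written for visual neuroscientists who want to understand, audit, or
simulate the behaviour of a standard pRF analysis: in particular how much
fitted pRF sizes can be trusted at fast (1 s TR) acquisitions, what the
noise ceiling says about attainable goodness-of-fit, and why temporal
low-pass filtering — though it raises R² — systematically inflates small
pRF-size estimates.

## The model

Each cortical vertex carries a pRF modelled as an isotropic 2D Gaussian in
visual-field coordinates, with centre (x₀, y₀) in degrees and size σ (the
Gaussian SD). The predicted neural response at frame *t* is the overlap of
the binary stimulus aperture with the pRF profile,

    n(t) = Σ_pixels  mask(t, p) · exp(−((p_x−x₀)² + (p_y−y₀)²) / 2σ²),

convolved with a canonical double-gamma HRF and z-scored. Fitting is
two-stage: an exhaustive grid search over 7,650 candidate predictions
(30 polar angles × 17 eccentricities × 15 σ values) maximising the Pearson
correlation with the observed series, then — when the coarse R² exceeds
0.01 — a Nelder–Mead refinement of (x₀, y₀, σ), followed by OLS for the
amplitude β₁ and baseline β₀. Because the criterion is a correlation, the
fit is invariant to the amplitude scale of the data: only response *shape*
informs the parameters.

Reliability is quantified per vertex by splitting the six runs into odd and
even halves, correlating the half-averages (r′), and applying the
Spearman–Brown prophecy formula r_obs = 2r′/(1+r′); the noise ceiling
ρ_o² = r_obs is the maximum R² any model could achieve, and R²/ρ_o² is the
noise-normalised goodness-of-fit. Cortical magnification (mm/deg) is
computed per vertex as √(cortical area)/√(visual area) over the polygon of
one-ring neighbours.

## Worked example

`examples/05_filtering_bias.py` runs the packaged filtering experiment
(20 vertices per condition, six runs of 250 frames at TR = 1 s, the
protocol's 0.38°/s bar step):

```
 true_sigma  filter_sd_s  median_sigma  median_r2  sigma_ratio  n_fit
      0.500          NaN         0.415      0.333        1.000     20
      0.500        1.000         0.567      0.612        1.368     20
      0.500        2.000         0.875      0.694        2.110     20
      2.500          NaN         2.324      0.277        1.000     20
      2.500        1.000         2.386      0.573        1.027     20
      2.500        2.000         2.529      0.709        1.089     20
```

Reading the table: low-pass filtering the data with a 2 s Gaussian kernel
roughly doubles the median fitted size of σ = 0.5° pRFs (ratio 2.11) while
leaving σ = 2.5° pRFs nearly unchanged (ratio 1.09), and the median R²
rises with the filter width in both regimes. The mechanism: a temporal blur
of SD k seconds blurs together responses to bar positions ~k·v degrees
apart (v = bar speed), which the model can only absorb by enlarging σ —
unless the pRF already spans adjacent bar positions. Filtering therefore
buys goodness-of-fit at the price of biased spatial-tuning estimates.

The other examples each demonstrate one capability (aperture generation,
forward modelling, parameter recovery, noise ceilings, cortical
magnification, the full two-site pipeline) and print what they compute.

A thin CLI wraps the library for shell use, e.g.:

```bash
prfpipe apertures --out apertures.nii.gz
prfpipe run --seed 7 --out results/demo
prfpipe experiment-filtering-bias --seed 7 --out filtering.tsv
```

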