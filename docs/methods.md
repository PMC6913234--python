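# Methods

This note documents the models, conventions, parameter choices, and known
limitations of prfpipe, in the spirit of a methods appendix.

## Stimulus design

The mapping stimulus is a bar of width 0.53° sweeping across a circular
aperture of diameter 19° in discrete 1 s steps; 8 sweeps per run with the
motion direction rotated 45° clockwise per sweep (starting bottom-to-top),
25 steps per sweep, 25 s blank baselines after sweeps 4 and 8, and 10 dummy
volumes before the first sweep (260 volumes acquired, 250 analysed).

The forward model consumes only the binary aperture: a `mask_resolution_px`
× `mask_resolution_px` grid spanning the aperture's bounding square
[−9.5°, +9.5°]², x rightward, y upward, origin at fixation, pixel centres
at (i+0.5)·Δ − 9.5 with Δ = 19/resolution. A pixel is on iff its centre
lies inside the bar strip, inside the circle, and outside the central
foveal hole (radius 0.53°, the unstimulated region around fixation). The
graded contrast ramps of the display stimulus are not modelled: the pRF
model is defined on a binary mask. Bars are infinite strips clipped by the
circle, matching a bar that spans the full screen height.

**Bar step size.** The protocol states a 0.38°/s step, but 25 × 0.38° =
9.5° covers only half the 19° aperture. Two modes are provided:
`"full-coverage"` (default for map-making) uses step = diameter/steps =
0.76° so that 25 steps traverse the aperture, consistent with maps reaching
9.5° eccentricity; `"literal"` uses 0.38° exactly as printed, mapping the
central strip. The filtering-bias experiment uses the literal mode — see
below for why this matters there and barely matters elsewhere.

At coarse mask resolutions the 0.53° bar can fall between pixel centres
(empty frames) when Δ > 0.53°; resolutions of 50 px (Δ = 0.38°) and up are
free of this. Tests run at 50 px; 100 px reproduces the acquisition-fidelity
mask of 10,000 pixels.

## Forward model

pRF: isotropic 2D Gaussian, weight(p) = exp(−‖p − c‖²/2σ²), unnormalised
(gain is irrelevant to a correlation fit, and the package's tests verify
the predicted series is invariant to positive rescaling of the profile).
Neural response per frame: mask × profile summed over pixels. HRF: the
canonical double-gamma (peak delay 6 s, undershoot delay 16 s, dispersions
1, peak:undershoot 6:1, duration 40 s, sampled at the TR), peak-normalised
to 1; empirically measured HRFs differ slightly between individuals but the
effect on pRF parameters is small, so the canonical form is the default and
all parameters are configurable. Convolution is causal and zero-padded,
truncated to the series length; the run starts with a sweep, so start-up
transients are benign. The prediction is z-scored; a prediction with no
effective stimulus overlap (total overlap weight below 1e−12) or zero
variance is *degenerate* and is represented as a flag (None / NaN), never
an exception, because the grid search must skip such candidates silently.

## Preprocessing

Per run and vertex: linear detrend (least squares) then z-scoring; runs are
then averaged; optionally the averaged series is convolved with a temporal
Gaussian of SD 1 or 2 s. Order is fixed: detrend → z-score → average →
filter → fit. The filter kernel is truncated at ±3 SD and renormalised to
unit sum (a constant series passes unchanged); edges use reflection
padding, avoiding endpoint attenuation on a finite scan. Implementation:
`scipy.ndimage.gaussian_filter1d`. Only the data are filtered, never the
model prediction — the size bias under study arises precisely from the
mismatch between blurred data and sharp predictor. Zero-variance vertices
propagate as NaN and are excluded from fitting, not silently zeroed.

## Fitting

Coarse stage: Pearson correlation of the observed series against 7,650
precomputed candidate predictions. The grid factorisation (the protocol
reports only the total) is 30 polar angles (12° spacing) × 17
eccentricities (log-spaced 0.25–9.5°) × 15 σ (log-spaced 0.1–5°), fully
configurable. Ties resolve to the first candidate in axis order
(determinism). Candidates with eccentricity > aperture radius + 2σ or
zero-variance predictions are flagged degenerate and skipped. The best
candidate enters the fine stage only if its R² (squared Pearson r) exceeds
0.01; the package exposes the three distinct thresholds used downstream as
named constants: 0.01 (fine-fit gate), 0.10 (map display/comparison), 0.15
(summary inclusion for pRF size and CMF).

Fine stage: Nelder–Mead over (x₀, y₀, log σ) maximising Pearson r — the
log-reparameterisation keeps σ positive — with parameter tolerance 1e−2°,
function tolerance 1e−6, at most 400 evaluations. If the optimiser ends
below the coarse correlation the coarse parameters are kept (stage
"coarse-only"). β₁/β₀ by OLS of the observed series on the final z-scored
prediction. R² is reported as squared Pearson correlation throughout.

## Reliability and the noise ceiling

Runs split by order index (1,3,5 vs 2,4,6), each half averaged after
per-run detrending/z-scoring, Pearson r′ between the halves per vertex,
Spearman–Brown step-up r_obs = 2r′/(1+r′) (the factor 2 is exact for
3-run halves of 6 runs), ceiling ρ_o² = r_obs assuming a perfectly reliable
predictor and true model. Negative r′ leaves the ceiling undefined (NaN)
rather than clamped — flags preserve information and callers can count
them. Normalised goodness-of-fit R²/ρ_o² may exceed 1 under sampling noise
and is not clipped (values above 1.5 trigger a warning). Correlating raw
half-averages versus re-z-scored ones is inconsequential: Pearson r is
affine-invariant.

With per-run signal-variance fraction v, the expected half-split
correlation is 3v/(1+2v) and the expected ceiling 6v/(1+5v), which equals
the explainable R² of the six-run average — the identity the ceiling tests
verify against a direct simulation oracle. Note the per-vertex ceiling and
the true model's achieved R² are two noisy estimates of the same quantity:
either may exceed the other vertex by vertex; the ceiling is an upper bound
in expectation, not pointwise.

## Surface metrics

CMF per vertex: one-ring neighbours ordered by angle around the vertex in
the patch plane; cortical area = absolute shoelace area of their positions,
visual area = shoelace area of their pRF centres traversed in the same
order; CMF = √cortical/√visual. Boundary vertices (open rings), vertices
with an undefined neighbour, and zero visual areas yield NaN;
self-intersecting visual polygons (map scatter) keep their absolute area
but are flagged `winding_inconsistent`. Smoothing is a Gaussian-weighted
mean (FWHM in mm, truncated at 3 SD) on within-patch Euclidean distance —
appropriate for the package's flat synthetic patches; geodesic/spherical
smoothing of folded cortical meshes is out of scope. Eccentricity summaries
use 1°-wide bins starting at 0.5° (half-open, final bin closed), mean for
pRF size and median otherwise, vertices with R² ≤ 0.15 excluded for size
and CMF, and 1,000 bootstrap resamples with the central 95% as the CI. Map
comparison restricts to vertices above R² 0.1 in both maps and uses the
Fisher–Lee circular correlation for polar angle (rotation-invariant; the
variant is a package choice) and Spearman's ρ for eccentricity.

## Synthetic data

`make_truth_layout` draws vertices area-uniformly in an eccentricity
annulus with σ = a + b·ecc (pRF size growing with eccentricity, as in
cortex). `simulate_runs` builds each run as amplitude × z-scored prediction
+ drift + white Gaussian noise; the drift (linear slope 0.5 plus a
0.3-amplitude sinusoid of 120 s period, identical across runs) exercises
the detrending stage, and the white noise models the dominant
high-frequency component of 1 s TR acquisitions. An AR(1) noise option is
deliberately absent: the package models the regime the analysis addresses.
Using the *z-scored* prediction as the signal (rather than the raw overlap
series) makes the explainable-variance fraction per run exactly
v = A²/(A²+σ_n²), independent of how much of the stimulus a pRF sees —
which the noise-ceiling validation relies on.

Default noise: σ_n = 3.7 at amplitude 1, i.e. v ≈ 0.068 and an expected
fitted R² of the six-run average of 6v/(1+5v) ≈ 0.30 — the regime of fast
1 s TR scans, where reported model fits are low. This value was set from
the closed form, not tuned.

`make_flat_mesh` builds a regular triangulated patch in mm with pRF centres
assigned by an invertible mapping: constant magnification M (true CMF = M
everywhere) or the conformal log-polar map w = k·log(z+a), whose
magnification is isotropic and analytically k/|z+a| = k·e^(−u/k) —
reducing to the familiar k/(ecc+a) on the horizontal meridian. (A naive
(k·ln(ecc+a), k·θ) construction is not conformal — its radial and
tangential magnifications differ — and admits no single analytic CMF;
this is why the conformal map is used.)

## The filtering-bias experiment

`filtering_bias_experiment` simulates vertices at fixed true σ (defaults
0.5° and 2.5°), fits after no filtering and after 1 s and 2 s filtering of
the averaged data, and reports median σ̂, median R², and the σ̂ ratio
against the unfiltered condition. A temporal Gaussian blur of SD k seconds
acts on the sweep response like a spatial blur of SD k·v degrees at bar
speed v, so approximately σ̂ ≈ √(σ² + (k·v)²). The experiment therefore
uses the protocol's literal 0.38°/s step: at that speed a 2 s kernel
corresponds to 0.76° of spatial blur — doubling σ̂ at σ = 0.5° while
changing σ = 2.5° by only a few percent, the reported asymmetry between
early (small-pRF) and higher (large-pRF) visual areas. At the 0.76°/s
full-coverage step the blur is 1.52° and even 2.5° pRFs would inflate
measurably (~16%), which is why the experiment's design choice matters.
Vertices are confined to eccentricity 1–4°, inside the centrally mapped
strip of the literal design.

## Simulation scales and numerical choices

Packaged experiments run at 50×50 masks, 250 frames, 6 runs, and 50–200
vertices — sizes chosen so each experiment completes in seconds to a
couple of minutes on one CPU while leaving the measured effects far from
their decision boundaries. Convolutions in the fitting path use direct
`np.convolve` so that coarse-grid and fine-fit predictions are bit-
consistent. All randomness flows from explicit integer seeds through
`numpy.random.default_rng`; there is no hidden global state, and rerunning
any experiment with the same seed is byte-identical.

## Known limitations

* **Size estimates at low SNR.** With white noise bringing the fitted R²
  of the run average to ~0.3, the Pearson-correlation surface over σ is
  extremely shallow for pRFs smaller than the bar step (the predicted
  waveform barely changes), so per-vertex σ̂ scatters widely and is biased
  downward (the argmax drifts toward sharp-prediction candidates). Measured
  on 200 simulated vertices: median |σ̂−σ|/σ ≈ 20% and median position
  error ≈ 0.6° at fitted R² ≈ 0.3, improving to ≈8% and 0.26° at R² ≈ 0.65.
  This is a property of correlation-maximisation fitting itself, shared by
  the analysis the package reimplements; binned summaries remain usable
  because the scatter largely averages out.
* The noiseless pipeline does not reach R² = 1: detrending removes the
  signal's own small linear component (as any real pipeline does), costing
  ~1% of variance on this design.
* Only isotropic Gaussian pRFs, a fixed canonical HRF, linear spatial
  summation, and white (plus slow-drift) noise are modelled; surround
  suppression, compressive summation, per-subject HRFs, and physiological
  noise spectra are out of scope.
* Surface operations assume flat patches; no spherical registration or
  geodesic distances.
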