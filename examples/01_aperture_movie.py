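"""Build the sweeping-bar aperture movie for one mapping run.

The protocol sweeps a 0.53°-wide bar across a 19° circular aperture in
1 s steps: 8 sweeps of 25 steps, the direction rotating 45° clockwise each
sweep, with 25 s blank baselines after sweeps 4 and 8 and 10 dummy volumes
up front.
"""

from prfpipe import BarDesign, generate_apertures
from prfpipe.design import aperture_coverage

design = BarDesign()
movie = generate_apertures(design, include_dummies=True)
trimmed = movie.without_dummies()

print(f"frames per run (with dummies):    {movie.n_frames}")
print(f"frames per run (analysis):        {trimmed.n_frames}")
print(f"bar step size (full coverage):    {design.step_size_deg:.2f} deg")
print(f"mask resolution:                  {design.mask_resolution_px} px "
      f"({design.deg_per_px:.2f} deg/px)")
print(f"aperture pixels swept by the bar: {100 * aperture_coverage(trimmed):.1f}%")

# 260 frames = 10 dummies + 8 sweeps × 25 steps + 2 baselines × 25 s; the
# bar union covers nearly the whole aperture (the foveal hole is never
# stimulated), which is what lets the grid search map eccentricities to 9.5°.
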