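"""Temporal low-pass filtering inflates small pRF-size estimates.

Filtering the data (never the model prediction) with a Gaussian kernel of
SD k seconds blurs responses to bar positions presented close in time —
equivalent to a spatial blur of roughly k·v degrees at bar speed v.  Small
pRFs therefore fit as larger ones, while pRFs already wider than the blur
barely change; R² rises in both cases because high-frequency noise is
removed.
"""

from prfpipe import filtering_bias_experiment

table = filtering_bias_experiment(n_vertices=20, seed=3)
print(table.to_string(index=False, float_format=lambda x: f"{x:.3f}"))

ratio_small = table.query("true_sigma == 0.5 and filter_sd_s == 2.0")["sigma_ratio"]
ratio_large = table.query("true_sigma == 2.5 and filter_sd_s == 2.0")["sigma_ratio"]
print(f"\n2 s filter inflates sigma=0.5 deg estimates by x{float(ratio_small.iloc[0]):.2f}")
print(f"2 s filter changes sigma=2.5 deg estimates by x{float(ratio_large.iloc[0]):.2f}")
print("Goodness-of-fit rises with filtering even where size estimates are biased.")
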