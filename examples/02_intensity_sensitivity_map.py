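"""Map a segmenter's sensitivity to intensity scale and offset.

An intensity-window segmenter is swept over the 17 x 17 scale/offset grid
(scales 1/5 .. 5, offsets -3 .. 3 in steps of 3/8). The resulting heat map
shows the diagonal band of scale/offset combinations that keep the target
tissue class inside the segmenter's window — the qualitative signature of
an intensity-tuned model.
"""

from segsense import (
    PhantomSpec,
    intensity_grid_case1,
    make_phantom,
    make_threshold_segmenter,
    map_summary,
    plot_heatmap,
    run_sensitivity,
)

phantom = make_phantom(PhantomSpec(shape=(48, 48, 48), rng_seed=0))
segmenter = make_threshold_segmenter(0.7, 1.3)  # window matched to the tissue class

smap = run_sensitivity(phantom, segmenter, intensity_grid_case1())
summary = map_summary(smap, label=1)

print(f"grid points:      {smap.grid.size}")
print(f"mean DSC:         {summary['mean']:.3f} +/- {summary['std']:.3f}")
print(f"max DSC:          {summary['max']:.3f} at (scale, offset) = {summary['argmax_values']}")
ident = smap.grid.identity_index()
print(f"DSC at identity (scale 1, offset 0): {smap.scores[1][ident]:.3f}")
print(f"grid cells tied at the maximum: {len(summary['argmax_ties'])} "
      "(the tolerance band: every scale/offset pair keeping the tissue in-window)")
plot_heatmap(smap, label=1, path="intensity_map.png")
print(
    "wrote intensity_map.png; the bright band marks perturbations the "
    "segmenter tolerates, the dark regions where performance collapses."
)
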