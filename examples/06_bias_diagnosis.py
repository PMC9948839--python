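"""Diagnose a training-sample orientation bias from a sensitivity map.

A template segmenter is built from a phantom pre-rotated by +20 degrees
about x (its "training sample" is misoriented). Sweeping the pristine
phantom over a rotation grid, the map's maximum lands not at the identity
but offset by exactly the injected bias — the argmax offset reads out how
the test data should be re-oriented for optimal segmentation.
"""

from segsense import (
    PhantomSpec,
    inject_orientation_bias,
    make_phantom,
    make_template_segmenter,
    map_summary,
    run_sensitivity,
)
from segsense.demo import orientation_bank, rotation_subgrid

phantom = make_phantom(PhantomSpec(shape=(48, 48, 48), rng_seed=0))
grid = rotation_subgrid(span=40, step=20)

biased_template = inject_orientation_bias(phantom, (20.0, 0.0, 0.0))
segmenter = make_template_segmenter(biased_template, orientation_bank(grid))

summary = map_summary(run_sensitivity(phantom, segmenter, grid), label=1)
print(f"injected bias:        +20.0 deg about x")
print(f"map argmax at:        {summary['argmax_values']} (x, y degrees)")
print(f"argmax offset:        {summary['argmax_offset']}")
print(
    "The off-center maximum recovers the injected orientation bias: "
    "rotating test inputs by this offset before segmentation would give "
    "the best performance."
)
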