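"""Compare rotation sensitivity with and without orientation augmentation.

Two template-matching toy segmenters are swept over a +/-40 degree x/y
rotation grid: one knows only the native orientation (a model trained
without rotation augmentation), the other carries a bank of candidate
orientations (a rotation-augmented model). The augmented map is flatter —
the variance of its DSC values over the grid is smaller.
"""

import numpy as np

from segsense import (
    PhantomSpec,
    make_phantom,
    make_template_segmenter,
    map_summary,
    run_sensitivity,
)
from segsense.demo import orientation_bank, rotation_subgrid

phantom = make_phantom(PhantomSpec(shape=(48, 48, 48), rng_seed=0))
grid = rotation_subgrid(span=40, step=20)  # 5 x 5 points

naive = run_sensitivity(phantom, make_template_segmenter(phantom, "identity_only"), grid)
bank = run_sensitivity(
    phantom, make_template_segmenter(phantom, orientation_bank(grid)), grid
)

for name, smap in [("identity-only", naive), ("orientation bank", bank)]:
    s = map_summary(smap, label=1)
    var = float(np.var(smap.scores[1]))
    print(f"{name:17s} mean DSC {s['mean']:.3f}  variance {var:.4f}")
print(
    "The orientation-bank segmenter keeps a high DSC across the whole "
    "grid (low variance): augmentation flattens the sensitivity map."
)
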