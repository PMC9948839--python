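"""Build a reference segmentation without ground truth using STAPLE.

Five simulated raters with known sensitivity/specificity mark a phantom
structure; the EM consensus recovers both the hidden truth and each
rater's performance parameters.
"""

from segsense import PhantomSpec, dice, make_phantom, simulate_raters, staple_consensus

phantom = make_phantom(
    PhantomSpec(shape=(64, 64, 64), ellipsoid_semiaxes_frac=(0.35, 0.22, 0.15), rng_seed=5)
)
truth = phantom.labels > 0
sens_true = [0.95, 0.9, 0.85, 0.8, 0.75]
spec_true = [0.99] * 5

raters = simulate_raters(truth, sens_true, spec_true, rng=17)
result = staple_consensus(raters)

print("rater  true p  est p   true q  est q")
for k, (pt, pe, qt, qe) in enumerate(
    zip(sens_true, result.sensitivities, spec_true, result.specificities)
):
    print(f"  {k}    {pt:.2f}   {pe:.4f}  {qt:.2f}   {qe:.4f}")
print(f"consensus vs truth DSC: {dice(truth, result.consensus_mask).dsc:.4f}")
print(f"EM iterations: {result.n_iterations} (converged: {result.converged})")
print(
    "The estimated p/q sit within a few thousandths of the generating "
    "values, and the consensus recovers the hidden structure."
)
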