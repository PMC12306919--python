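"""Detect stress-coupled neural synchrony with Anna Karenina IS-RSA.

The generator couples each subject's shared-signal weight to a latent
stress trait (w from 0.05 up to 0.45 across the stress range), so pairs
of high-stress subjects synchronize more.  IS-RSA correlates the
pairwise neural similarity (Fisher-z ISC) with the AnnaK behavioral
similarity (pair mean of min-max-normalized stress) and tests it with a
subject-level Mantel permutation test.
"""

import numpy as np

from iscpipe import (
    SyntheticConfig,
    annak_similarity,
    generate_timeseries,
    mantel_permutation_test,
    pairwise_isc,
)

cfg = SyntheticConfig(
    n_subjects=40,
    run_lengths=(300,),
    run_names=("video",),
    n_rois=1,
    base_shared_fraction=0.05,
    annak_coupling=0.40,  # w spans 0.05 .. 0.45 over the stress range
    seed=11,
)
ts, truth = generate_timeseries(cfg)

neural = pairwise_isc(ts.data[:, 0, :], subjects=ts.subjects)
behav = annak_similarity(truth.latent_stress, "annak_mean", subjects=ts.subjects)

rho, p = mantel_permutation_test(neural, behav, n_permutations=2000, seed=11)
print(f"IS-RSA Spearman rho: {rho:.3f}")
print(f"Mantel permutation p (2000 permutations): {p:.4f}")
print()
print("rho > 0: behaviorally similar (jointly high-stress) pairs are also")
print("neurally similar -- the coupling the generator planted. With")
print("annak_coupling = 0 the same analysis returns rho near 0 and uniform p.")
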