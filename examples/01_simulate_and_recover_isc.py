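"""Generate a synthetic cohort with a known shared-signal fraction and
recover it with pairwise ISC.

Every subject's ROI series is sqrt(w)*c(t) + sqrt(1-w)*noise, so the
population correlation between any two subjects is w itself when all
share the same weight.  The back-transformed mean Fisher-z over all
subject pairs should therefore land near w.
"""

import numpy as np

from iscpipe import (
    SyntheticConfig,
    bootstrap_isc_test,
    generate_timeseries,
    pairwise_isc,
    summarize_isc,
)

cfg = SyntheticConfig(
    n_subjects=30,
    run_lengths=(540,),
    run_names=("session",),
    n_rois=1,
    base_shared_fraction=0.25,  # the ground truth to recover
    seed=7,
)
ts, truth = generate_timeseries(cfg)

matrix = pairwise_isc(ts.data[:, 0, :], subjects=ts.subjects,
                      roi="demo", condition="session")
isc = summarize_isc(matrix)
res = bootstrap_isc_test(matrix, n_iterations=1000, seed=7)

print(f"generative shared fraction w : 0.25")
print(f"recovered ISC (mean-z, back-transformed): {isc:.4f}")
print(f"subject-wise bootstrap p (1000 iterations): {res.p:.4f}")
print()
print("The recovered ISC estimates w; the bootstrap p at its floor of")
print("1/(B+1) says the observed synchrony is far outside the resampled null.")
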