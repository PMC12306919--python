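# iscpipe

Intersubject correlation (ISC) and intersubject representational
similarity analysis (IS-RSA) for naturalistic fMRI, with a synthetic-data
generator that makes every stage verifiable by parameter recovery.

## The problem

When different people watch the same video, stimulus-locked processing
shows up as correlated activity time courses across brains.  **ISC**
quantifies this: for one region of interest (ROI) and one stimulus, the
Pearson correlation `r_ij` between subjects *i* and *j*'s time series is
computed for every pair, Fisher-z-transformed (`z = atanh r`), and
summarized per ROI (mean z, back-transformed).  Significance uses a
subject-wise bootstrap: subjects are resampled with replacement, the
pairwise matrix is re-indexed, self-pairs created by duplication are
excluded, and the re-centered bootstrap summaries form the null.

**IS-RSA** then asks whether a trait explains who synchronizes with whom:
the Spearman correlation between the subject-pair triangle of the neural
similarity matrix and that of a behavioral similarity matrix.  For traits
like perceived stress the behavioral similarity follows the **Anna
Karenina** model — all high-trait pairs alike, low-trait subjects
idiosyncratic — operationalized as `sim(i,j) = (s̃_i + s̃_j)/2` (or
`min(s̃_i, s̃_j)`) on min-max-normalized scores.  Inference is a
subject-level Mantel permutation test.

Condition comparisons (e.g. three videos) use Friedman omnibus tests and
Wilcoxon signed-rank post hocs with the subject pair as observation unit,
and Benjamini–Hochberg FDR across ROIs.  The target design this package
emulates: 72 subjects, 16 spherical 6-mm stress-processing ROIs at MNI
coordinates, three ~3-minute ASMR videos plus a control video at TR = 1 s,
a 6-item perceived-stress scale, and viewing-habit questions.

Because a study of this kind rarely deposits raw data, the package
includes a generator in which subject *i*'s series is
`√w_i·c(t) + √(1−w_i)·ε_i(t)` with common signal `c` — so the population
correlation between two subjects is exactly `√(w_i·w_j)`, giving every
estimator a closed-form oracle, and an optional stress coupling
`w_i = clip(w₀ + β·s̃_i, 0, 0.95)` plants recoverable AnnaK structure.

## Worked example

```python
from iscpipe import (SyntheticConfig, generate_timeseries, pairwise_isc,
                     summarize_isc, bootstrap_isc_test)

cfg = SyntheticConfig(n_subjects=30, run_lengths=(540,), run_names=("session",),
                      n_rois=1, base_shared_fraction=0.25, seed=7)
ts, truth = generate_timeseries(cfg)
m = pairwise_isc(ts.data[:, 0, :], subjects=ts.subjects)
print(summarize_isc(m))                      # 0.2270
print(bootstrap_isc_test(m, 1000, seed=7).p) # 0.0010
```

The recovered ISC (0.227) estimates the generative shared fraction
w = 0.25 — the remaining gap is sampling noise at T = 540 — and the
bootstrap p of 0.0010 ≈ 1/(B+1) is the smallest attainable value,
meaning the observed synchrony exceeded every re-centered resample.
The `examples/` directory walks through ROI mask construction
(`02_roi_extraction.py`), AnnaK IS-RSA (`03_annak_isrsa.py`) and the
full battery (`04_full_pipeline.py`).

A thin CLI wraps the pipeline:

```bash
iscpipe simulate --out fixture/                 # write a synthetic dataset
iscpipe validate fixture/                       # check it for consistency
iscpipe run --config analysis.yaml --out out/   # run the full battery
```

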