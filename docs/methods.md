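# Methods

## Generative model for synthetic cohorts

The generator produces subject × ROI × time ensembles with the
statistical structure that intersubject analyses presuppose.  For
subject *i*, ROI *v*, run *r*:

    x_i(t) = sqrt(w_i) · c(t) + sqrt(1 − w_i) · ε_i(t)

where `c` (one realization per ROI × run, shared by all subjects) and
`ε_i` (idiosyncratic) are zero-mean, unit-variance Gaussian processes.
Under this model the population Pearson correlation between subjects
*i* and *j* is exactly `sqrt(w_i · w_j)`, which is the closed-form
oracle every recovery test checks against.

Temporal autocorrelation: both `c` and `ε` pass through an AR(1) filter
(default coefficient 0.3, scaled back to unit stationary variance).
ISC itself is invariant to this shared smoothness, but resampling-based
inference is not, so fMRI-like smoothness belongs in the default
conditions.  TR is 1 s; the default design is 72 subjects, 16 ROIs,
three 180-s stimulus runs plus one 180-s control run.

Anna Karenina coupling: a latent standard-normal stress trait is
min-max normalized over the sample to `s̃ ∈ [0, 1]` and raises the
subject's weight, `w_i = clip(w₀ + β·s̃_i, 0, 0.95)`.  The 0.95 ceiling
keeps pairwise correlations away from 1 so the Fisher transform stays
finite without relying on clipping.  Min-max (rather than rank)
normalization keeps the clipping interpretable: β is the exact spread
of weights across the observed stress range.

Likert items: each of the 6 stress items is a latent
`y_k = sqrt(ρ)·s + sqrt(1−ρ)·e_k` cut at the equal-probability normal
quintiles into levels 1–5.  `ρ` ("interitem_corr") parameterizes the
*latent* scale; on the latent scale Cronbach's α follows
Spearman–Brown, `α = kρ/(1+(k−1)ρ)`, and 5-level discretization
attenuates the observed inter-item correlation by roughly 10%, so
simulated α sits slightly below the latent closed form (ρ = 0.4, k = 6
gives α ≈ 0.77 observed vs 0.75 latent).  We deliberately do not
compensate: the parameter is a latent-scale quantity and the
attenuation is a property of Likert measurement worth keeping visible.

What the generator does **not** emulate: voxel-level hemodynamics,
motion or physiological artifacts, non-Gaussian signal distributions,
inter-ROI spatial correlation, or run-order randomization across
subjects.  Passing recovery tests therefore show the *estimators and
tests* behave as designed under the assumed model — not that real
ASMR-viewing cohorts satisfy that model.

## ISC

Pairwise ISC for one ROI/condition is the n×n matrix of Pearson
correlations between subjects' series, clipped to ±(1 − 1e−7) and
Fisher-z-transformed; the diagonal is undefined.  The per-ROI summary
is the mean z over the n(n−1)/2 unique pairs, back-transformed with
tanh (median available).  Concatenated-session ISC z-scores each run
per subject per ROI before joining, so runs contribute covariance, not
mean shifts, and duplicating a run leaves ISC unchanged.

Subject-wise bootstrap: each iteration draws n subjects with
replacement and re-indexes the stored z matrix; off-diagonal cells
that refer to the same original subject twice are excluded (their
r = 1 reflects duplication, not synchrony).  The null distribution is
the bootstrap summaries minus their mean, and the two-sided p uses the
+1 correction, so the attainable floor is 1/(B+1).  Default B = 5000.

**Known property — conservativeness.** Under the global null the
pairwise z entries are mutually uncorrelated, so the sampling SD of the
mean-z is σ/√P over P pairs; subject resampling duplicates subjects
and hence pair entries, and the bootstrap dispersion of the summary
overshoots the sampling dispersion by a measured factor of ~1.9.  The
test's measured type-I rate at α = 0.05 on null cohorts (n = 20,
T = 200) is therefore ≈ 0.000–0.005: it never inflates false
positives, but it is strongly conservative.  Users wanting nominal
calibration should treat bootstrap p-values as upper-bound-valid;
power against genuine shared signal remains high because a true effect
pushes the observed summary far outside the resampled null.

Condition and group comparisons: the Friedman omnibus (tie-corrected
χ², df = k−1) and Wilcoxon signed-rank post hocs (zeros dropped,
average ranks, tie-corrected normal approximation, W = min(W⁺, W⁻))
take the unordered subject pair as the observation unit.  Pairs
sharing a subject are dependent; this pair-level convention is used
deliberately and flagged in every report manifest.  Group ISC
differences (e.g. willing vs unwilling viewers) compare within-group
mean z (between-group pairs unused) against a label-permutation null
with group sizes fixed; groups below 3 subjects are refused.
Multiplicity is handled with Benjamini–Hochberg FDR, family = the ROIs
within each analysis.

## IS-RSA

The IS-RSA score is the Spearman correlation (average ranks) between
the strict upper triangles of the neural z matrix and the behavioral
similarity matrix.  Constant triangles raise an explicit error rather
than returning 0.  Inference permutes subject labels of the behavioral
matrix jointly over rows and columns (entries sharing a subject are
dependent, so independent entry shuffling would be anticonservative)
and recomputes ρ; default 5000 permutations, two-sided +1 p.  The
condition battery corrects across the ROI family within each condition.
The AnnaK variant default is the pair mean, with the pair minimum as an
option — both canonical forms are implemented because the underlying
similarity model admits either; the choice is a config key.
Profile contrasts between conditions (each video vs the control video)
use a classic paired t over the per-ROI ρ profiles, df = n_ROIs − 1.

## ROI geometry

ROIs are spheres (default diameter 6 mm, i.e. radius 3 mm) at MNI mm
coordinates.  A voxel belongs to a mask iff its *center* lies within
the radius, inclusive boundary — the simplest reproducible convention;
any-overlap dialects can be compared against it.  The voxel→mm affine
is authoritative; no axis-orientation guessing.  On a 2-mm isotropic
grid with the center on a voxel center this yields 19 voxels (1 at
distance 0, 6 at 2.0 mm, 12 at 2.83 mm; 3.46 mm is excluded), which
the tests verify against a brute-force lattice scan.  Spatial
reduction is the unweighted mean over mask voxels (the most common
default where the choice is unstated); NaN voxels are ignored per time
point, and an all-NaN time point yields NaN with a warning.

The shipped 16-ROI stress table is stored verbatim from its published
source, including two internal inconsistencies (two insula rows whose
left/right labels disagree with the sign of x, and a left-amygdala z
of +14 against the right homologue's −14).  These are flagged in CSV
comments and deliberately not "corrected".  Because anatomical labels
repeat, uniqueness is enforced on (label, x, y, z) and analyses index
ROIs by the derived key `label [x, y, z]`.

## Behavioral scoring

The composite stress score is the plain mean of the 6 items (range
1–5); reverse-keying (x → 6−x) is exposed but defaults to none, since
the emulated instrument's keying is unstated.  Cronbach's α uses
sample variances (n−1).  Missing items exclude the subject listwise —
never imputed — and all percentage summaries report count and
denominator explicitly (denominators in such studies often differ from
the scanned n, and the pipeline surfaces rather than assumes them).
Percentages print as round(100·count/denominator).

## Numerical and design choices

- Correlations clipped at 1 − 1e−7 before atanh; duplicate series give
  a large finite z, never infinity.
- All randomized procedures take explicit integer seeds; derived seeds
  are generated with `numpy.random.SeedSequence` or fixed offsets, kept
  below 2³¹, and recorded in every result row and manifest.
- Degenerate bootstrap resamples (all pairs excluded) are redrawn,
  counted, and warned about.
- The all-tied Friedman case short-circuits to χ² = 0, p = 1 (the
  tie-corrected statistic is 0/0 there).
- The pipeline aborts on the first failing stage with a stage-named
  error; partial outputs are not written.

## Validation studies and problem sizes

`iscpipe.studies` (exercised by the test suite and
`scripts/acceptance.py`) runs: ISC recovery at w = 0.25 averaged over
10 cohorts of n = 30, T = 540 (the average suppresses the ±0.012
per-cohort sampling SD of the estimator); bootstrap type-I rate over
200 null cohorts (n = 20, T = 200, 1000 iterations); AnnaK Mantel
power over 50 cohorts (n = 40, T = 300, w spanning 0.05–0.45, 500
permutations) and null calibration over 200 cohorts (KS test for
uniform p); and cross-video detection over 50 cohorts (one video at
w = 0.15 vs two at 0.05, n = 30, 16 ROIs, FDR across ROIs).  These
sizes were chosen so each study estimates its rate with adequate
Monte-Carlo precision while the whole battery completes in well under
a minute on one CPU.

## Limitations

- The bootstrap conservativeness described above is inherent to the
  subject-wise resampling construction on pairwise matrices.
- Pair-level Friedman/Wilcoxon tests ignore dependence between pairs
  sharing a subject; their nominal p-values are optimistic for
  between-condition nulls and should be read with the FDR step and the
  report caveat in mind.
- No leave-one-out ISC, voxel-level ISC maps, sliding-window ISC,
  partial Mantel with covariates, or psychometrics beyond α.
- Inputs are assumed already in MNI space; no registration or
  preprocessing is performed.
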