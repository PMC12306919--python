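"""Pairwise intersubject correlation (ISC) and its inference.

The central object is the subject x subject matrix of Fisher
z-transformed Pearson correlations between ROI time series, computed
per ROI and per condition.  Significance of its summary uses a
subject-wise bootstrap: subjects are resampled with replacement, the
stored matrix is re-indexed, self-pairs created by duplication are
dropped, and the re-centered bootstrap summaries form the null.
Condition comparisons use Friedman / Wilcoxon tests with subject pairs
as the observation unit, and multiplicity across ROIs is handled with
Benjamini-Hochberg FDR.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, ValidationError, DegenerateDataError

__all__ = [
    "SubjectTimeseriesSet",
    "PairwiseIscMatrix",
    "BootstrapResult",
    "pairwise_isc",
    "concatenate_runs",
    "summarize_isc",
    "bootstrap_isc_test",
    "friedman_across_conditions",
    "wilcoxon_signed_rank",
    "bh_fdr",
    "group_isc_difference",
]

#: correlations are clipped to +/- (1 - R_CLIP_EPS) before atanh so that
#: duplicate series yield a large finite z instead of infinity
R_CLIP_EPS = 1e-7


@dataclass
class SubjectTimeseriesSet:
    """Subjects x ROIs x time with named run segments.

    ``data`` has shape (n_subjects, n_rois, n_time); ``runs`` maps a
    segment name to ``(start, length)`` in samples, identical across
    subjects.  ``tr`` is the sampling interval in seconds.
    """

    subjects: list[str]
    roi_labels: list[str]
    data: np.ndarray
    runs: dict[str, tuple[int, int]]
    tr: float = 1.0

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 3:
            raise ValidationError("data must be (subjects, rois, time)")
        n, r, t = self.data.shape
        if n != len(self.subjects):
            raise ValidationError("subject list does not match data shape")
        if r != len(self.roi_labels):
            raise ValidationError("ROI label list does not match data shape")
        for name, (start, length) in self.runs.items():
            if start < 0 or length < 3 or start + length > t:
                raise ValidationError(
                    f"run '{name}' (start={start}, length={length}) does not fit "
                    f"in {t} time points (runs need length >= 3)"
                )

    @property
    def n_subjects(self) -> int:
        return self.data.shape[0]

    @property
    def n_rois(self) -> int:
        return self.data.shape[1]

    def run_slice(self, name: str) -> slice:
        if name not in self.runs:
            raise ValidationError(f"unknown run segment '{name}'")
        start, length = self.runs[name]
        return slice(start, start + length)

    def segment(self, name: str) -> np.ndarray:
        """Data restricted to one named run, shape (subjects, rois, length)."""
        return self.data[:, :, self.run_slice(name)]


@dataclass
class PairwiseIscMatrix:
    """Symmetric subject x subject matrix of Fisher-z ISC values for one
    ROI and condition.  The diagonal is undefined and stored as NaN."""

    roi: str
    condition: str
    subjects: list[str]
    z: np.ndarray

    def __post_init__(self) -> None:
        self.z = np.asarray(self.z, dtype=float)
        n = len(self.subjects)
        if self.z.shape != (n, n):
            raise ValidationError("z must be square and match the subject list")
        if n < 3:
            raise ValidationError("pairwise ISC needs at least 3 subjects")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.z[off], self.z.T[off], equal_nan=True):
            raise ValidationError("z must be symmetric off the diagonal")
        if not np.all(np.isfinite(self.z[off])):
            raise ValidationError("off-diagonal z values must be finite")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def triangle(self) -> np.ndarray:
        """Strict upper-triangle z values as a flat vector (n(n-1)/2 pairs)."""
        iu = np.triu_indices(self.n_subjects, k=1)
        return self.z[iu]

    def r_matrix(self) -> np.ndarray:
        """Back-transformed correlation matrix (NaN diagonal preserved)."""
        return np.tanh(self.z)


@dataclass
class BootstrapResult:
    """Subject-wise bootstrap test of one ROI/condition ISC summary."""

    roi: str
    condition: str
    observed_isc: float  # back-transformed r scale
    p: float
    n_iterations: int
    seed: int
    summary: str = "mean_z"
    q: float | None = None
    n_degenerate: int = 0


def pairwise_isc(
    ts: np.ndarray,
    subjects: list[str] | None = None,
    roi: str = "",
    condition: str = "",
) -> PairwiseIscMatrix:
    """Pairwise Pearson correlations between every pair of subjects' series,
    Fisher z-transformed.

    Parameters
    ----------
    ts : array (n_subjects, n_time) for a single ROI and condition.
    """
    ts = np.asarray(ts, dtype=float)
    if ts.ndim != 2:
        raise ValidationError("expected a (subjects, time) array for one ROI")
    n, t = ts.shape
    if n < 3:
        raise ValidationError("pairwise ISC needs at least 3 subjects")
    if t < 3:
        raise ValidationError("pairwise ISC needs at least 3 time points")
    if subjects is None:
        subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    if np.any(~np.isfinite(ts)):
        bad = np.unique(np.nonzero(~np.isfinite(ts))[0])
        names = ", ".join(subjects[i] for i in bad)
        raise ValidationError(f"non-finite values in series of: {names}")
    sd = ts.std(axis=1)
    if np.any(sd == 0):
        names = ", ".join(subjects[i] for i in np.nonzero(sd == 0)[0])
        raise ValidationError(f"constant time series for: {names}")
    r = np.corrcoef(ts)
    r = np.clip(r, -(1 - R_CLIP_EPS), 1 - R_CLIP_EPS)
    z = np.arctanh(r)
    np.fill_diagonal(z, np.nan)
    return PairwiseIscMatrix(roi=roi, condition=condition, subjects=list(subjects), z=z)


def concatenate_runs(
    ts_set: SubjectTimeseriesSet,
    segments: list[str],
    per_run_standardize: bool = True,
    name: str = "concat",
) -> SubjectTimeseriesSet:
    """Join named run segments into a single segment, in the given order.

    With ``per_run_standardize`` (the default) each segment is z-scored
    per subject per ROI before joining, so runs contribute equally
    regardless of their raw scale; ISC on the concatenation then pools
    within-run covariance rather than between-run mean shifts.
    """
    if not segments:
        raise ValidationError("need at least one segment name")
    pieces = []
    for seg in segments:
        block = ts_set.segment(seg)
        if per_run_standardize:
            mu = block.mean(axis=2, keepdims=True)
            sd = block.std(axis=2, keepdims=True)
            if np.any(sd == 0):
                sub_idx, roi_idx = np.nonzero(sd[:, :, 0] == 0)[:2]
                raise ValidationError(
                    f"constant segment '{seg}' for subject "
                    f"{ts_set.subjects[sub_idx[0]]}, ROI {ts_set.roi_labels[roi_idx[0]]}"
                )
            block = (block - mu) / sd
        pieces.append(block)
    data = np.concatenate(pieces, axis=2)
    return SubjectTimeseriesSet(
        subjects=list(ts_set.subjects),
        roi_labels=list(ts_set.roi_labels),
        data=data,
        runs={name: (0, data.shape[2])},
        tr=ts_set.tr,
    )


def _summarize_triangle(tri_z: np.ndarray, method: str) -> float:
    if method == "mean_z":
        return float(np.tanh(np.mean(tri_z)))
    if method == "median_z":
        return float(np.tanh(np.median(tri_z)))
    raise ParameterError(f"unknown summary method '{method}'")


def summarize_isc(matrix: PairwiseIscMatrix, method: str = "mean_z") -> float:
    """Single ISC value per ROI: mean (or median) Fisher z over unique
    subject pairs, back-transformed to the correlation scale."""
    return _summarize_triangle(matrix.triangle(), method)


def bootstrap_isc_test(
    matrix: PairwiseIscMatrix,
    n_iterations: int = 5000,
    seed: int = 0,
    summary: str = "mean_z",
) -> BootstrapResult:
    """Subject-wise bootstrap significance of the ISC summary.

    Each iteration draws n subjects with replacement and re-indexes the
    stored z matrix.  Off-diagonal cells that refer to the same original
    subject twice (self-pairs) are excluded, since their r = 1 reflects
    duplication, not synchrony.  The null distribution is the bootstrap
    summaries re-centered at zero; the two-sided p-value uses the +1
    finite-sample correction, so its floor is 1/(n_iterations+1).
    """
    if n_iterations < 100:
        raise ParameterError("n_iterations must be at least 100")
    n = matrix.n_subjects
    z = matrix.z
    observed_z = np.arctanh(_summarize_triangle(matrix.triangle(), summary))

    rng = np.random.default_rng(seed)
    iu = np.triu_indices(n, k=1)
    stats_boot = np.empty(n_iterations)
    n_degenerate = 0
    batch = 1000
    done = 0
    while done < n_iterations:
        b = min(batch, n_iterations - done)
        idx = rng.integers(0, n, size=(b, n))
        # resampled pair values and self-pair exclusion mask, vectorized
        pair_vals = z[idx[:, iu[0]], idx[:, iu[1]]]  # (b, n_pairs)
        valid = idx[:, iu[0]] != idx[:, iu[1]]
        n_valid = valid.sum(axis=1)
        degenerate = n_valid == 0
        while np.any(degenerate):  # redraw all-self-pair resamples
            n_degenerate += int(degenerate.sum())
            redraw = rng.integers(0, n, size=(int(degenerate.sum()), n))
            idx[degenerate] = redraw
            pair_vals[degenerate] = z[redraw[:, iu[0]], redraw[:, iu[1]]]
            valid[degenerate] = redraw[:, iu[0]] != redraw[:, iu[1]]
            n_valid = valid.sum(axis=1)
            degenerate = n_valid == 0
        if summary == "mean_z":
            s = np.where(valid, pair_vals, 0.0).sum(axis=1) / n_valid
        else:
            s = np.array(
                [np.median(pair_vals[i, valid[i]]) for i in range(b)]
            )
        stats_boot[done:done + b] = s
        done += b

    null = stats_boot - stats_boot.mean()
    p = (1.0 + np.sum(np.abs(null) >= abs(observed_z))) / (n_iterations + 1.0)
    if n_degenerate:
        warnings.warn(
            f"{n_degenerate} degenerate bootstrap resamples redrawn", stacklevel=2
        )
    return BootstrapResult(
        roi=matrix.roi,
        condition=matrix.condition,
        observed_isc=float(np.tanh(observed_z)),
        p=float(p),
        n_iterations=n_iterations,
        seed=seed,
        summary=summary,
        n_degenerate=n_degenerate,
    )


def _aligned_triangles(matrices: list[PairwiseIscMatrix]) -> np.ndarray:
    subjects = matrices[0].subjects
    for m in matrices[1:]:
        if m.subjects != subjects:
            raise ValidationError("all conditions must share the same subject set")
    return np.column_stack([m.triangle() for m in matrices])  # (n_pairs, k)


def friedman_across_conditions(
    matrices: list[PairwiseIscMatrix],
) -> tuple[float, int, float]:
    """Friedman omnibus test of ISC differences across k >= 3 conditions.

    The observation unit is the unordered subject pair: each pair
    contributes one z value per condition, ranked within pair with
    average ranks for ties (tie-corrected chi-square).  Pairs sharing a
    subject are not independent; this matches common practice for
    pairwise-ISC condition comparisons and is flagged in reports.
    """
    k = len(matrices)
    if k < 3:
        raise ParameterError(
            "Friedman test needs at least 3 conditions; use wilcoxon_signed_rank for 2"
        )
    tri = _aligned_triangles(matrices)
    if np.all(tri.max(axis=1) == tri.min(axis=1)):  # all ranks tied in every pair
        return 0.0, k - 1, 1.0
    chi2, p = stats.friedmanchisquare(*[tri[:, c] for c in range(k)])
    return float(chi2), k - 1, float(p)


def wilcoxon_signed_rank(x: np.ndarray, y: np.ndarray) -> tuple[float, float, float]:
    """Two-sided Wilcoxon signed-rank test on paired values.

    Zero differences are dropped; ``W`` is the smaller of the positive
    and negative rank sums; the z statistic uses the tie-corrected
    normal approximation.  Returns ``(W, z, p)``.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("x and y must be 1-D and of equal length")
    d = x - y
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; p set to 1", stacklevel=2)
        return 0.0, 0.0, 1.0
    res = stats.wilcoxon(
        x, y, zero_method="wilcox", correction=False, alternative="two-sided",
        method="approx",
    )
    return float(res.statistic), float(res.zstatistic), float(res.pvalue)


def bh_fdr(pvalues) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values, in the input order.

    q_(i) = min_{j>=i} m p_(j) / j, capped at 1; elementwise q >= p.
    """
    p = np.asarray(pvalues, dtype=float)
    if p.size == 0:
        raise ParameterError("empty p-value list")
    if np.any((p <= 0) | (p > 1)):
        raise ParameterError("p-values must lie in (0, 1]")
    _, q, _, _ = multipletests(p, method="fdr_bh")
    return q


def group_isc_difference(
    ts: np.ndarray,
    labels: np.ndarray,
    n_permutations: int = 5000,
    seed: int = 0,
    subjects: list[str] | None = None,
    roi: str = "",
    condition: str = "",
) -> tuple[float, float]:
    """Permutation test of within-group ISC differences for one ROI.

    Observed statistic: mean within-group-A z minus mean within-group-B z
    (between-group pairs are unused).  The null permutes group labels
    over subjects with group sizes fixed.  Returns ``(observed_diff, p)``.
    """
    labels = np.asarray(labels).astype(bool)
    n = ts.shape[0]
    if labels.shape != (n,):
        raise ParameterError("labels must be one binary value per subject")
    if labels.sum() < 3 or (~labels).sum() < 3:
        raise ValidationError(
            "each group needs at least 3 subjects for within-group ISC"
        )
    m = pairwise_isc(ts, subjects=subjects, roi=roi, condition=condition)
    z = m.z
    iu = np.triu_indices(n, k=1)
    pair_vals = z[iu]

    def stat(lab: np.ndarray) -> float:
        a = lab[iu[0]] & lab[iu[1]]
        b = ~lab[iu[0]] & ~lab[iu[1]]
        return float(pair_vals[a].mean() - pair_vals[b].mean())

    observed = stat(labels)
    rng = np.random.default_rng(seed)
    count = 0
    lab = labels.copy()
    for _ in range(n_permutations):
        rng.shuffle(lab)
        if abs(stat(lab)) >= abs(observed):
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return observed, float(p)
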