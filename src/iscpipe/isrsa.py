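"""Intersubject representational similarity analysis (IS-RSA).

IS-RSA asks whether subjects who are behaviorally similar are also
neurally similar: the Spearman rank correlation between the strict
upper triangles of a subject x subject neural-similarity matrix
(pairwise Fisher-z ISC) and a behavioral-similarity matrix (e.g. Anna
Karenina stress similarity).  Inference is a Mantel-style permutation
test: subject labels of the behavioral matrix are permuted jointly over
rows and columns -- triangle entries sharing a subject are dependent, so
shuffling entries independently would be anticonservative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.stats import rankdata, t as t_dist

from .behavioral import SimilarityMatrix
from .errors import ParameterError, ValidationError, DegenerateDataError
from .isc import PairwiseIscMatrix, bh_fdr

__all__ = [
    "IsrsaResult",
    "isrsa_score",
    "mantel_permutation_test",
    "paired_t_profile",
    "isrsa_battery",
]


@dataclass
class IsrsaResult:
    """Spearman rho between neural and behavioral similarity for one
    ROI/condition, with permutation p and BH-FDR q."""

    roi: str
    condition: str
    rho: float
    p: float
    n_permutations: int
    seed: int
    q: float | None = None


def _check_aligned(neural: PairwiseIscMatrix, behav: SimilarityMatrix) -> None:
    if neural.subjects != behav.subjects:
        raise ValidationError("neural and behavioral subject orderings differ")
    if neural.n_subjects < 4:
        raise ValidationError("IS-RSA needs at least 4 subjects")


def _spearman_from_ranked(ranked_x: np.ndarray, y: np.ndarray) -> float:
    """Pearson correlation of pre-ranked x with rankdata(y)."""
    ry = rankdata(y)
    rx = ranked_x
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    denom = np.sqrt((rx @ rx) * (ry @ ry))
    if denom == 0:
        raise DegenerateDataError("constant similarity triangle; rho undefined")
    return float((rx @ ry) / denom)


def isrsa_score(neural: PairwiseIscMatrix, behav: SimilarityMatrix) -> float:
    """Spearman rank correlation between the two vectorized strict upper
    triangles (average ranks for ties).

    A constant behavioral triangle makes the correlation undefined and
    raises :class:`DegenerateDataError` rather than returning 0.
    """
    _check_aligned(neural, behav)
    x = neural.triangle()
    y = behav.triangle()
    if np.all(y == y[0]):
        raise DegenerateDataError("constant behavioral triangle; rho undefined")
    if np.all(x == x[0]):
        raise DegenerateDataError("constant neural triangle; rho undefined")
    return _spearman_from_ranked(rankdata(x), y)


def mantel_permutation_test(
    neural: PairwiseIscMatrix,
    behav: SimilarityMatrix,
    n_permutations: int = 5000,
    seed: int = 0,
) -> tuple[float, float]:
    """Subject-level (Mantel) permutation test of the IS-RSA score.

    Rows and columns of the behavioral matrix are permuted jointly with a
    random subject relabeling; rho is recomputed each time.  Two-sided
    p = (1 + #{|rho_perm| >= |rho_obs|}) / (n_permutations + 1).
    Returns ``(rho_observed, p)``.
    """
    if n_permutations < 100:
        raise ParameterError("n_permutations must be at least 100")
    _check_aligned(neural, behav)
    n = neural.n_subjects
    x = neural.triangle()
    if np.all(x == x[0]):
        raise DegenerateDataError("constant neural triangle; rho undefined")
    ranked_x = rankdata(x)
    B = behav.values
    iu = np.triu_indices(n, k=1)
    y = B[iu]
    if np.all(y == y[0]):
        raise DegenerateDataError("constant behavioral triangle; rho undefined")
    observed = _spearman_from_ranked(ranked_x, y)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = rng.permutation(n)
        yp = B[np.ix_(perm, perm)][iu]
        if abs(_spearman_from_ranked(ranked_x, yp)) >= abs(observed):
            count += 1
    p = (1.0 + count) / (n_permutations + 1.0)
    return observed, float(p)


def paired_t_profile(scores_a, scores_b) -> tuple[float, int, float]:
    """Paired-samples t test on ROI-wise score profiles.

    Each ROI contributes one (a, b) pair; df = n_rois - 1.  Used to ask
    whether an IS-RSA profile is systematically higher in one condition
    than another (e.g. ASMR vs control video).
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1 or a.size < 2:
        raise ParameterError("need two equal-length 1-D profiles (>= 2 entries)")
    d = a - b
    sd = d.std(ddof=1)
    n = d.size
    if sd == 0:
        if np.all(d == 0):
            return 0.0, n - 1, 1.0
        raise DegenerateDataError("zero-variance nonzero differences")
    t = d.mean() / (sd / np.sqrt(n))
    df = n - 1
    p = 2.0 * t_dist.sf(abs(t), df)
    return float(t), df, float(p)


def isrsa_battery(
    neural_matrices: dict[str, dict[str, PairwiseIscMatrix]],
    behav: SimilarityMatrix,
    n_permutations: int = 5000,
    seed: int = 0,
) -> list[IsrsaResult]:
    """IS-RSA for every ROI x condition, with BH-FDR across ROIs within
    each condition family.

    ``neural_matrices`` maps condition -> {roi_key -> PairwiseIscMatrix}
    (conditions typically the per-video segments plus the concatenated
    session).  Each (condition, ROI) gets its own derived permutation
    seed so results are reproducible yet independent.
    """
    results: list[IsrsaResult] = []
    for c_idx, (condition, per_roi) in enumerate(sorted(neural_matrices.items())):
        family: list[IsrsaResult] = []
        for r_idx, (roi_key, matrix) in enumerate(sorted(per_roi.items())):
            sub_seed = (seed + 10_007 * c_idx + 101 * r_idx) % (2**31)
            rho, p = mantel_permutation_test(
                matrix, behav, n_permutations=n_permutations, seed=sub_seed
            )
            family.append(
                IsrsaResult(
                    roi=roi_key, condition=condition, rho=rho, p=p,
                    n_permutations=n_permutations, seed=sub_seed,
                )
            )
        q = bh_fdr([r.p for r in family])
        for r, qv in zip(family, q):
            r.q = float(qv)
        results.extend(family)
    return results
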