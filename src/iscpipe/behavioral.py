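"""Perceived-stress scoring, reliability, and behavioral similarity matrices.

The stress questionnaire is a 6-item, 5-point Likert scale; the composite
score is the item mean (reverse-keying optional).  For IS-RSA the
per-subject scores are turned into a subject x subject similarity matrix
under the Anna Karenina model: pairs of *high*-trait subjects are
similar, pairs of low-trait subjects are not, operationalized as either
the pair mean or the pair minimum of min-max-normalized scores.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, ValidationError, DegenerateDataError

__all__ = [
    "SimilarityMatrix",
    "score_stress",
    "cronbach_alpha",
    "annak_similarity",
    "frequency_similarity",
    "describe_sample",
]

ANNAK_VARIANTS = ("annak_mean", "annak_min")


@dataclass
class SimilarityMatrix:
    """Subject x subject behavioral similarity; diagonal undefined (NaN)."""

    subjects: list[str]
    values: np.ndarray
    metric: str

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.subjects)
        if self.values.shape != (n, n):
            raise ValidationError("values must be square and match subjects")
        off = ~np.eye(n, dtype=bool)
        if not np.allclose(self.values[off], self.values.T[off]):
            raise ValidationError("similarity matrix must be symmetric")

    @property
    def n_subjects(self) -> int:
        return len(self.subjects)

    def triangle(self) -> np.ndarray:
        iu = np.triu_indices(self.n_subjects, k=1)
        return self.values[iu]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.subjects, columns=self.subjects)


def _item_matrix(items) -> np.ndarray:
    arr = np.asarray(items, dtype=float)
    if arr.ndim != 2:
        raise ValidationError("items must be a subjects x items table")
    if np.any(~np.isfinite(arr)):
        raise ValidationError("missing item responses; subjects must be excluded "
                              "listwise, not imputed")
    return arr


def score_stress(items, reverse_keys: set[int] | None = None) -> np.ndarray:
    """Composite stress score: mean of the (possibly reverse-keyed) items.

    ``reverse_keys`` holds 0-based item column indices whose responses are
    mapped x -> 6 - x before averaging.  All responses must be integers in
    1..5; missing or out-of-range values raise rather than being imputed.
    """
    arr = _item_matrix(items)
    if np.any((arr < 1) | (arr > 5)) or np.any(arr != np.round(arr)):
        raise ValidationError("item responses must be integers in 1..5")
    if reverse_keys:
        bad = [k for k in reverse_keys if not 0 <= k < arr.shape[1]]
        if bad:
            raise ParameterError(f"reverse_keys out of range: {bad}")
        arr = arr.copy()
        for k in reverse_keys:
            arr[:, k] = 6 - arr[:, k]
    return arr.mean(axis=1)


def cronbach_alpha(items) -> float:
    """Cronbach's alpha: k/(k-1) * (1 - sum of item variances / variance of sums).

    Sample variances use the n-1 denominator.  Raises
    :class:`DegenerateDataError` when the total-score variance is zero
    (alpha undefined).
    """
    arr = _item_matrix(items)
    n, k = arr.shape
    if k < 2:
        raise ParameterError("alpha needs at least 2 items")
    if n < 3:
        raise ParameterError("alpha needs at least 3 subjects")
    total_var = arr.sum(axis=1).var(ddof=1)
    if total_var == 0:
        raise DegenerateDataError("zero total-score variance; alpha undefined")
    item_var = arr.var(axis=0, ddof=1).sum()
    return float(k / (k - 1) * (1.0 - item_var / total_var))


def _normalize(scores: np.ndarray, method: str) -> np.ndarray:
    if method == "minmax":
        lo, hi = scores.min(), scores.max()
        if hi == lo:
            raise DegenerateDataError(
                "constant scores: min-max normalization undefined"
            )
        return (scores - lo) / (hi - lo)
    if method == "rank":
        from scipy.stats import rankdata

        r = rankdata(scores)  # average ranks for ties
        if np.all(r == r[0]):
            raise DegenerateDataError("constant scores: rank normalization undefined")
        return (r - 1) / (len(r) - 1)
    raise ParameterError(f"unknown normalization '{method}'")


def annak_similarity(
    scores,
    variant: str = "annak_mean",
    subjects: list[str] | None = None,
    normalization: str = "minmax",
) -> SimilarityMatrix:
    """Anna Karenina similarity on per-subject trait scores.

    Scores are normalized to [0, 1] over the analyzed sample (min-max by
    default, ranks optionally), then

    - ``annak_mean``: sim(i, j) = (s_i + s_j) / 2
    - ``annak_min`` : sim(i, j) = min(s_i, s_j)

    Both make all high-trait pairs alike (similarity near 1) while
    low-trait pairs are dissimilar -- the "every unhappy family is
    unhappy in its own way" geometry.
    """
    if variant not in ANNAK_VARIANTS:
        raise ParameterError(f"variant must be one of {ANNAK_VARIANTS}")
    scores = np.asarray(scores, dtype=float)
    if scores.ndim != 1 or scores.size < 3:
        raise ValidationError("need a 1-D score vector for >= 3 subjects")
    s = _normalize(scores, normalization)
    if variant == "annak_mean":
        sim = (s[:, None] + s[None, :]) / 2.0
    else:
        sim = np.minimum(s[:, None], s[None, :])
    np.fill_diagonal(sim, np.nan)
    if subjects is None:
        subjects = [f"sub-{i + 1:03d}" for i in range(scores.size)]
    return SimilarityMatrix(subjects=list(subjects), values=sim, metric=variant)


def frequency_similarity(
    freqs, variant: str = "annak_mean", subjects: list[str] | None = None,
    normalization: str = "minmax",
) -> SimilarityMatrix:
    """AnnaK similarity on self-reported viewing frequency (1..5)."""
    freqs = np.asarray(freqs, dtype=float)
    if np.any((freqs < 1) | (freqs > 5)):
        raise ValidationError("frequencies must lie in 1..5")
    return annak_similarity(
        freqs, variant=variant, subjects=subjects, normalization=normalization
    )


def describe_sample(table: pd.DataFrame, reverse_keys: set[int] | None = None) -> dict:
    """Descriptive statistics for a behavioral table.

    Numeric variables get mean, SD (n-1) and range; binary flags get
    ``100 * count / denominator`` rounded to the nearest integer, with
    the count and denominator reported alongside (denominators are
    surfaced, never assumed, since subjects with missing responses are
    dropped per variable).
    """
    if len(table) == 0:
        raise ValidationError("empty behavioral table")
    out: dict[str, dict] = {}

    item_cols = [c for c in table.columns if c.startswith("item")]
    if item_cols:
        items = table[item_cols].dropna()
        comp = score_stress(items.to_numpy(), reverse_keys)
        out["composite_stress"] = {
            "n": int(len(comp)),
            "mean": float(np.mean(comp)),
            "sd": float(np.std(comp, ddof=1)) if len(comp) > 1 else 0.0,
            "min": float(np.min(comp)),
            "max": float(np.max(comp)),
        }
        if len(items) >= 3:
            try:
                out["composite_stress"]["cronbach_alpha"] = cronbach_alpha(
                    items.to_numpy()
                )
            except DegenerateDataError:
                out["composite_stress"]["cronbach_alpha"] = None

    if "freq" in table.columns:
        f = table["freq"].dropna().to_numpy(dtype=float)
        out["freq"] = {
            "n": int(f.size),
            "mean": float(f.mean()),
            "sd": float(f.std(ddof=1)) if f.size > 1 else 0.0,
            "min": float(f.min()),
            "max": float(f.max()),
        }

    flag_cols = [c for c in table.columns if c == "willing" or c.startswith("familiar")]
    for c in flag_cols:
        col = table[c].dropna()
        count = int(col.sum())
        denom = int(len(col))
        out[c] = {
            "count": count,
            "denominator": denom,
            "percent": binary_percent(count, denom),
        }
    return out


def binary_percent(count: int, denominator: int) -> int:
    """Percentage as the paper-style integer: round(100 * count / denom)."""
    if denominator <= 0:
        raise ParameterError("denominator must be positive")
    return int(round(100.0 * count / denominator))
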