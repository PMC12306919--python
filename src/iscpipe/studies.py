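"""Simulation studies that validate the pipeline against its own
generative model: parameter recovery, bootstrap type-I calibration,
Anna Karenina power and null calibration, and cross-video detection.

Each study generates data with :mod:`iscpipe.synthetic`, runs the
corresponding estimator or test, and reports the aggregate the study is
designed to measure.  All studies are deterministic given their seed.
"""

from __future__ import annotations

import numpy as np
from scipy.stats import kstest

from .behavioral import annak_similarity
from .isc import (
    bh_fdr,
    bootstrap_isc_test,
    friedman_across_conditions,
    pairwise_isc,
    summarize_isc,
    wilcoxon_signed_rank,
)
from .isrsa import mantel_permutation_test
from .synthetic import SyntheticConfig, generate_timeseries

__all__ = [
    "isc_recovery_study",
    "bootstrap_type1_study",
    "annak_power_study",
    "annak_null_study",
    "crossvideo_detection_study",
]


def _seed_seq(seed: int, n: int) -> list[int]:
    return [int(s) for s in
            np.random.SeedSequence(seed).generate_state(n) % (2**31)]


def isc_recovery_study(
    n_subjects: int = 30,
    n_time: int = 540,
    w: float = 0.25,
    n_datasets: int = 10,
    seed: int = 0,
) -> float:
    """Mean back-transformed mean-z ISC over replicate datasets in which
    every subject shares weight ``w``; the estimand is ``w`` itself."""
    vals = []
    for s in _seed_seq(seed, n_datasets):
        cfg = SyntheticConfig(
            n_subjects=n_subjects, run_lengths=(n_time,), run_names=("v",),
            n_rois=1, base_shared_fraction=w, seed=s,
        )
        ts, _ = generate_timeseries(cfg)
        vals.append(summarize_isc(pairwise_isc(ts.data[:, 0, :])))
    return float(np.mean(vals))


def bootstrap_type1_study(
    n_datasets: int = 200,
    n_subjects: int = 20,
    n_time: int = 200,
    n_iterations: int = 1000,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Rejection rate of the subject-wise bootstrap on pure-noise data
    (w = 0); a calibrated test stays near ``alpha``."""
    rejections = 0
    for s in _seed_seq(seed, n_datasets):
        cfg = SyntheticConfig(
            n_subjects=n_subjects, run_lengths=(n_time,), run_names=("v",),
            n_rois=1, base_shared_fraction=0.0, seed=s,
        )
        ts, _ = generate_timeseries(cfg)
        m = pairwise_isc(ts.data[:, 0, :])
        res = bootstrap_isc_test(m, n_iterations=n_iterations, seed=s ^ 0x5A5A)
        rejections += res.p < alpha
    return rejections / n_datasets


def _annak_dataset(n_subjects, n_time, w_low, w_high, seed):
    cfg = SyntheticConfig(
        n_subjects=n_subjects, run_lengths=(n_time,), run_names=("v",),
        n_rois=1, base_shared_fraction=w_low,
        annak_coupling=w_high - w_low, seed=seed,
    )
    ts, truth = generate_timeseries(cfg)
    return ts, truth


def annak_power_study(
    n_sims: int = 50,
    n_subjects: int = 40,
    n_time: int = 300,
    w_low: float = 0.05,
    w_high: float = 0.45,
    n_permutations: int = 500,
    alpha: float = 0.05,
    seed: int = 0,
) -> float:
    """Fraction of simulations in which the Mantel test detects the
    stress-coupled synchrony (behavioral similarity = annak_mean on the
    generating stress trait)."""
    hits = 0
    for s in _seed_seq(seed, n_sims):
        ts, truth = _annak_dataset(n_subjects, n_time, w_low, w_high, s)
        m = pairwise_isc(ts.data[:, 0, :], subjects=ts.subjects)
        sim = annak_similarity(truth.latent_stress, "annak_mean",
                               subjects=ts.subjects)
        _, p = mantel_permutation_test(m, sim, n_permutations=n_permutations,
                                       seed=s ^ 0x3C3C)
        hits += p < alpha
    return hits / n_sims


def annak_null_study(
    n_sims: int = 200,
    n_subjects: int = 40,
    n_time: int = 300,
    w: float = 0.05,
    n_permutations: int = 500,
    seed: int = 0,
) -> tuple[np.ndarray, float]:
    """Mantel p-values with zero stress coupling (beta = 0); returns the
    p-values and the Kolmogorov-Smirnov p for uniformity on (0, 1]."""
    pvals = []
    for s in _seed_seq(seed, n_sims):
        ts, truth = _annak_dataset(n_subjects, n_time, w, w, s)
        m = pairwise_isc(ts.data[:, 0, :], subjects=ts.subjects)
        sim = annak_similarity(truth.latent_stress, "annak_mean",
                               subjects=ts.subjects)
        _, p = mantel_permutation_test(m, sim, n_permutations=n_permutations,
                                       seed=s ^ 0x3C3C)
        pvals.append(p)
    pvals = np.asarray(pvals)
    ks_p = float(kstest(pvals, "uniform").pvalue)
    return pvals, ks_p


def crossvideo_detection_study(
    n_sims: int = 50,
    n_subjects: int = 30,
    n_rois: int = 16,
    run_length: int = 180,
    w_elevated: float = 0.15,
    w_baseline: float = 0.05,
    alpha: float = 0.05,
    seed: int = 0,
) -> dict:
    """One video with elevated shared signal vs two baseline videos.

    Per simulation: Friedman omnibus per ROI with BH-FDR across ROIs,
    then Wilcoxon post hocs.  Reports the fraction of simulations where
    the first ROI's Friedman q < alpha, and -- among those -- the
    fraction where the post hocs single out the elevated video (both
    comparisons against it significant at alpha, with the elevated
    video's mean z the largest).
    """
    w0 = np.tile([w_elevated, w_baseline, w_baseline], (n_rois, 1))
    detected = 0
    singled_out = 0
    for s in _seed_seq(seed, n_sims):
        cfg = SyntheticConfig(
            n_subjects=n_subjects, run_lengths=(run_length,) * 3,
            run_names=("v1", "v2", "v3"), n_rois=n_rois,
            base_shared_fraction=w0, seed=s,
        )
        ts, _ = generate_timeseries(cfg)
        ps = []
        matrices = {}
        for r in range(n_rois):
            ms = [pairwise_isc(ts.segment(v)[:, r, :], subjects=ts.subjects,
                               roi=f"roi{r}", condition=v)
                  for v in ("v1", "v2", "v3")]
            matrices[r] = ms
            _, _, p = friedman_across_conditions(ms)
            ps.append(p)
        q = bh_fdr(ps)
        if q[0] < alpha:
            detected += 1
            tri = [m.triangle() for m in matrices[0]]
            _, _, p12 = wilcoxon_signed_rank(tri[0], tri[1])
            _, _, p13 = wilcoxon_signed_rank(tri[0], tri[2])
            means = [t.mean() for t in tri]
            if (p12 < alpha and p13 < alpha
                    and means[0] == max(means)):
                singled_out += 1
    return {
        "detection_rate": detected / n_sims,
        "posthoc_singles_out_rate": (singled_out / detected) if detected else 0.0,
        "n_sims": n_sims,
    }
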