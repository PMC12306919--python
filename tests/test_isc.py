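"""Pairwise ISC, run concatenation, subject-wise bootstrap, Friedman /
Wilcoxon condition tests and BH-FDR, each against an independent oracle
or a hand-computed example."""

import numpy as np
import pytest

from iscpipe import (
    PairwiseIscMatrix,
    SubjectTimeseriesSet,
    bh_fdr,
    bootstrap_isc_test,
    concatenate_runs,
    friedman_across_conditions,
    group_isc_difference,
    pairwise_isc,
    summarize_isc,
    wilcoxon_signed_rank,
)
from iscpipe.errors import ParameterError, ValidationError
from iscpipe.isc import R_CLIP_EPS


def matrix_from_triangle(tri, n, roi="r", condition="c"):
    """Build a PairwiseIscMatrix from strict-upper-triangle values."""
    z = np.zeros((n, n))
    iu = np.triu_indices(n, 1)
    z[iu] = tri
    z = z + z.T
    np.fill_diagonal(z, np.nan)
    return PairwiseIscMatrix(roi=roi, condition=condition,
                             subjects=[f"s{i}" for i in range(n)], z=z)


class TestPairwiseIsc:
    def test_identical_series_clip_to_finite_z(self, rng):
        base = rng.standard_normal(50)
        ts = np.stack([base, base, rng.standard_normal(50)])
        m = pairwise_isc(ts)
        assert m.z[0, 1] == pytest.approx(np.arctanh(1 - R_CLIP_EPS))
        assert np.isfinite(m.z[0, 1])

    def test_orthogonal_sinusoids_give_zero(self):
        t = np.linspace(0, 2 * np.pi, 400, endpoint=False)
        ts = np.stack([np.sin(t), np.cos(t), np.sin(2 * t)])
        m = pairwise_isc(ts)
        assert abs(np.tanh(m.z[0, 1])) < 1e-10

    def test_three_subjects_three_pairs(self, rng):
        m = pairwise_isc(rng.standard_normal((3, 30)))
        assert m.triangle().shape == (3,)

    def test_constant_series_error_names_subject(self, rng):
        ts = rng.standard_normal((4, 30))
        ts[2] = 5.0
        with pytest.raises(ValidationError, match="sub-003"):
            pairwise_isc(ts)

    def test_too_short_or_too_few(self, rng):
        with pytest.raises(ValidationError):
            pairwise_isc(rng.standard_normal((2, 30)))
        with pytest.raises(ValidationError):
            pairwise_isc(rng.standard_normal((4, 2)))

    def test_affine_invariance(self, rng):
        ts = rng.standard_normal((5, 40))
        scaled = ts * rng.uniform(0.5, 3.0, size=(5, 1)) + rng.normal(size=(5, 1))
        a, b = pairwise_isc(ts), pairwise_isc(scaled)
        iu = np.triu_indices(5, 1)
        assert np.allclose(a.z[iu], b.z[iu], atol=1e-10)

    def test_subject_reordering_permutes_matrix(self, rng):
        ts = rng.standard_normal((5, 40))
        perm = rng.permutation(5)
        a = pairwise_isc(ts)
        b = pairwise_isc(ts[perm])
        off = ~np.eye(5, dtype=bool)
        assert np.allclose(np.where(off, a.z, 0)[np.ix_(perm, perm)],
                           np.where(off, b.z, 0), atol=1e-12)
        assert summarize_isc(a) == pytest.approx(summarize_isc(b))


class TestConcatenateRuns:
    def _ts(self, rng, lengths=(40, 40), names=("a", "b"), n=4):
        data = rng.standard_normal((n, 2, sum(lengths)))
        offs = np.cumsum([0, *lengths])
        runs = {nm: (int(offs[i]), lengths[i]) for i, nm in enumerate(names)}
        return SubjectTimeseriesSet(
            subjects=[f"s{i}" for i in range(n)], roi_labels=["r1", "r2"],
            data=data, runs=runs,
        )

    def test_duplicated_run_leaves_isc_unchanged(self, rng):
        ts = self._ts(rng)
        single = concatenate_runs(ts, ["a"])
        double = concatenate_runs(ts, ["a", "a"])
        assert double.data.shape[2] == 2 * single.data.shape[2]
        m1 = pairwise_isc(single.data[:, 0, :])
        m2 = pairwise_isc(double.data[:, 0, :])
        iu = np.triu_indices(4, 1)
        assert np.allclose(m1.z[iu], m2.z[iu], atol=1e-10)

    def test_each_segment_standardized(self, rng):
        ts = self._ts(rng)
        out = concatenate_runs(ts, ["a", "b"])
        first = out.data[:, :, :40]
        assert np.allclose(first.mean(axis=2), 0.0, atol=1e-12)
        assert np.allclose(first.std(axis=2), 1.0, atol=1e-12)

    def test_missing_segment_errors(self, rng):
        with pytest.raises(ValidationError, match="nope"):
            concatenate_runs(self._ts(rng), ["nope"])


class TestSummarize:
    def test_constant_z_backtransforms(self):
        m = matrix_from_triangle(np.full(6, 0.1), 4)
        assert summarize_isc(m) == pytest.approx(np.tanh(0.1))

    def test_constant_r_recovered(self, rng):
        c = 0.37
        m = matrix_from_triangle(np.full(10, np.arctanh(c)), 5)
        assert summarize_isc(m) == pytest.approx(c)

    def test_antisymmetric_values_cancel(self):
        m = matrix_from_triangle(np.array([0.3, -0.3, 0.2, -0.2, 0.1, -0.1]), 4)
        assert summarize_isc(m) == pytest.approx(0.0, abs=1e-12)

    def test_median_option(self):
        m = matrix_from_triangle(np.array([0.1, 0.1, 0.1, 0.1, 0.1, 5.0]), 4)
        assert summarize_isc(m, "median_z") == pytest.approx(np.tanh(0.1))


class TestBootstrap:
    def test_near_perfect_synchrony_attains_minimum_p(self, rng):
        shared = rng.standard_normal(200)
        ts = np.sqrt(0.95) * shared + np.sqrt(0.05) * rng.standard_normal((10, 200))
        m = pairwise_isc(ts)
        res = bootstrap_isc_test(m, n_iterations=500, seed=3)
        assert res.p == pytest.approx(1.0 / 501.0)

    def test_determinism_and_seed_sensitivity(self, small_dataset):
        _, ts, _ = small_dataset
        m = pairwise_isc(ts.segment("video1")[:, 0, :])
        a = bootstrap_isc_test(m, n_iterations=300, seed=7)
        b = bootstrap_isc_test(m, n_iterations=300, seed=7)
        c = bootstrap_isc_test(m, n_iterations=300, seed=8)
        assert a.p == b.p
        assert abs(a.p - c.p) < 0.2  # differs only by Monte-Carlo noise

    def test_too_few_iterations_rejected(self, small_dataset):
        _, ts, _ = small_dataset
        m = pairwise_isc(ts.segment("video1")[:, 0, :])
        with pytest.raises(ParameterError):
            bootstrap_isc_test(m, n_iterations=50)

    def test_recovery_of_generative_weight(self):
        # all subjects share w = 0.25 -> back-transformed mean z ~ 0.25
        from iscpipe import SyntheticConfig, generate_timeseries

        cfg = SyntheticConfig(n_subjects=30, run_lengths=(540,),
                              run_names=("v",), n_rois=1,
                              base_shared_fraction=0.25, seed=42)
        ts, _ = generate_timeseries(cfg)
        val = summarize_isc(pairwise_isc(ts.data[:, 0, :]))
        assert abs(val - 0.25) < 0.05


class TestFriedman:
    def test_identical_conditions_give_zero(self, rng):
        tri = rng.standard_normal(10)
        ms = [matrix_from_triangle(tri, 5, condition=f"c{i}") for i in range(3)]
        chi2, df, p = friedman_across_conditions(ms)
        assert chi2 == 0.0 and df == 2 and p == 1.0

    def test_hand_computed_rank_sums(self):
        # 3 pairs, conditions valued 1 < 2 < 3 in every pair:
        # rank sums (3, 6, 9) -> chi2 = 12/(3*3*4) * sum(R^2) - 3*3*4 = 6
        ms = [matrix_from_triangle(np.full(3, v), 3, condition=f"c{v}")
              for v in (0.1, 0.2, 0.3)]
        chi2, df, p = friedman_across_conditions(ms)
        assert chi2 == pytest.approx(6.0)
        assert df == 2

    def test_pair_count_matches_subjects(self, rng):
        n = 12
        ms = [matrix_from_triangle(rng.standard_normal(n * (n - 1) // 2), n)
              for _ in range(3)]
        assert ms[0].triangle().size == 66

    def test_two_conditions_redirects_to_wilcoxon(self, rng):
        ms = [matrix_from_triangle(rng.standard_normal(6), 4) for _ in range(2)]
        with pytest.raises(ParameterError, match="wilcoxon"):
            friedman_across_conditions(ms)

    def test_mismatched_subjects_error(self, rng):
        a = matrix_from_triangle(rng.standard_normal(6), 4)
        b = matrix_from_triangle(rng.standard_normal(6), 4)
        b.subjects = ["x0", "x1", "x2", "x3"]
        c = matrix_from_triangle(rng.standard_normal(6), 4)
        with pytest.raises(ValidationError):
            friedman_across_conditions([a, b, c])


class TestWilcoxon:
    def test_identical_pairs_give_p_one(self):
        x = np.arange(8, dtype=float)
        with pytest.warns(UserWarning):
            W, z, p = wilcoxon_signed_rank(x, x)
        assert p == 1.0

    def test_all_positive_differences(self):
        y = np.zeros(5)
        x = np.array([1.0, 2, 3, 4, 5])
        W, z, p = wilcoxon_signed_rank(x, y)
        assert W == 0.0  # W- = 0 is the smaller rank sum

    def test_hand_ranked_example(self):
        # d = (+1, -2, +3, -4, +5): ranks 1..5, W+ = 9, W- = 6, W = 6
        x = np.array([1.0, -2, 3, -4, 5])
        W, z, p = wilcoxon_signed_rank(x, np.zeros(5))
        assert W == pytest.approx(6.0)
        assert 0 < p <= 1


class TestBhFdr:
    @staticmethod
    def stepup_oracle(p):
        """Independent step-up: q_(i) = min_{j >= i} m p_(j) / j via loops."""
        p = np.asarray(p, dtype=float)
        m = p.size
        order = np.argsort(p, kind="stable")
        q_sorted = np.empty(m)
        for i in range(m):
            q_sorted[i] = min(
                min(m * p[order[j]] / (j + 1) for j in range(i, m)), 1.0
            )
        q = np.empty(m)
        q[order] = q_sorted
        return q

    def test_hand_example(self):
        q = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(q, 0.04)

    def test_single_p(self):
        assert bh_fdr([0.2])[0] == pytest.approx(0.2)

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(30):
            p = rng.uniform(1e-6, 1.0, size=rng.integers(1, 11))
            assert np.allclose(bh_fdr(p), self.stepup_oracle(p), atol=1e-12)

    def test_q_dominates_p_and_monotone(self, rng):
        p = rng.uniform(1e-6, 1, size=10)
        q = bh_fdr(p)
        assert np.all(q >= p - 1e-15)
        order = np.argsort(p)
        assert np.all(np.diff(q[order]) >= -1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(ParameterError):
            bh_fdr([])
        with pytest.raises(ParameterError):
            bh_fdr([0.0, 0.5])


class TestGroupDifference:
    def test_detects_group_structure(self, rng):
        # group A shares a signal (w = 0.4), group B is pure noise
        T = 300
        shared = rng.standard_normal(T)
        a = np.sqrt(0.4) * shared + np.sqrt(0.6) * rng.standard_normal((10, T))
        b = rng.standard_normal((10, T))
        ts = np.vstack([a, b])
        labels = np.array([1] * 10 + [0] * 10)
        diff, p = group_isc_difference(ts, labels, n_permutations=300, seed=5)
        assert diff > 0
        assert p < 0.05

    def test_small_group_rejected(self, rng):
        ts = rng.standard_normal((6, 50))
        with pytest.raises(ValidationError):
            group_isc_difference(ts, np.array([1, 1, 0, 0, 0, 0]), 200, 0)

    def test_relabeling_symmetry(self, rng):
        ts = rng.standard_normal((12, 80))
        labels = np.array([1] * 6 + [0] * 6)
        perm = rng.permutation(12)
        d1, p1 = group_isc_difference(ts, labels, n_permutations=200, seed=9)
        d2, p2 = group_isc_difference(ts[perm], labels[perm],
                                      n_permutations=200, seed=9)
        assert d1 == pytest.approx(d2, abs=1e-12)
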