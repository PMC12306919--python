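"""Generator contracts: shapes, ranges, closed-form correlation oracle,
reliability of simulated Likert items, determinism, fixture round trips."""

import json

import numpy as np
import pytest

from iscpipe import (
    SyntheticConfig,
    expected_pairwise_correlation,
    generate_stress_items,
    generate_timeseries,
    load_fixture,
    write_fixture,
)
from iscpipe.behavioral import cronbach_alpha
from iscpipe.errors import DataFormatError, ParameterError
from iscpipe.synthetic import effective_weights, generate_behavioral_table


class TestStressItems:
    def test_shape_and_range(self):
        items, latent = generate_stress_items(72, 6, 0.4, seed=1)
        assert items.shape == (72, 6)
        assert latent.shape == (72,)
        vals = items.to_numpy()
        assert vals.min() >= 1 and vals.max() <= 5
        assert np.all(vals == np.round(vals))

    def test_alpha_follows_spearman_brown(self):
        # latent inter-item r = 0.4, k = 6 -> alpha ~ 6*0.4/(1+5*0.4) = 0.75
        items, _ = generate_stress_items(2000, 6, 0.4, seed=3)
        alpha = cronbach_alpha(items.to_numpy())
        assert abs(alpha - 0.75) < 0.05

    def test_near_unit_correlation_gives_near_unit_alpha(self):
        items, _ = generate_stress_items(500, 6, 0.99, seed=5)
        assert cronbach_alpha(items.to_numpy()) > 0.95

    @pytest.mark.parametrize("bad", [-0.1, 1.0, 1.5])
    def test_invalid_correlation_rejected(self, bad):
        with pytest.raises(ParameterError):
            generate_stress_items(10, 6, bad)

    def test_too_few_items_rejected(self):
        with pytest.raises(ParameterError):
            generate_stress_items(10, 1, 0.4)


class TestExpectedCorrelation:
    @pytest.mark.parametrize(
        "wi, wj, expected",
        [(0.25, 0.25, 0.25), (0.0, 0.7, 0.0), (0.16, 0.36, 0.24), (1.0, 1.0, 1.0)],
    )
    def test_closed_form(self, wi, wj, expected):
        assert expected_pairwise_correlation(wi, wj) == pytest.approx(expected)

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            expected_pairwise_correlation(-0.1, 0.5)
        with pytest.raises(ParameterError):
            expected_pairwise_correlation(0.5, 1.1)


class TestGenerateTimeseries:
    def test_empirical_correlation_matches_oracle(self):
        # w_i = 0.16, w_j = 0.36 via w0 + beta * normalized stress
        cfg = SyntheticConfig(
            n_subjects=2, run_lengths=(5000,), run_names=("v",), n_rois=1,
            base_shared_fraction=0.16, annak_coupling=0.20, seed=9,
        )
        ts, truth = generate_timeseries(cfg, latent_stress=np.array([0.0, 1.0]))
        assert truth.effective_weight[0, 0, 0] == pytest.approx(0.16)
        assert truth.effective_weight[1, 0, 0] == pytest.approx(0.36)
        r = np.corrcoef(ts.data[0, 0], ts.data[1, 0])[0, 1]
        assert abs(r - 0.24) < 0.03

    def test_no_shared_signal_gives_zero_isc(self):
        from iscpipe import pairwise_isc

        cfg = SyntheticConfig(
            n_subjects=15, run_lengths=(400,), run_names=("v",), n_rois=1,
            base_shared_fraction=0.0, seed=2,
        )
        ts, _ = generate_timeseries(cfg)
        z = pairwise_isc(ts.data[:, 0, :]).triangle()
        # mean z is ~N(0, sigma/sqrt(n_eff)); allow 3 standard errors with
        # a conservative effective-pair count of n_subjects
        se = z.std() / np.sqrt(cfg.n_subjects)
        assert abs(z.mean()) < 3 * se + 1e-3

    def test_full_weight_clipped_to_ceiling(self):
        cfg = SyntheticConfig(
            n_subjects=5, run_lengths=(2000,), run_names=("v",), n_rois=1,
            base_shared_fraction=1.0, seed=4,
        )
        ts, truth = generate_timeseries(cfg)
        assert np.all(truth.effective_weight == 0.95)
        r = np.corrcoef(ts.data[:, 0, :])
        iu = np.triu_indices(5, 1)
        assert np.all(np.abs(r[iu] - 0.95) < 0.03)

    def test_unit_variance_and_zero_mean(self):
        cfg = SyntheticConfig(
            n_subjects=4, run_lengths=(5000, 5000), run_names=("a", "b"),
            n_rois=2, base_shared_fraction=0.3, seed=6,
        )
        ts, _ = generate_timeseries(cfg)
        for seg in ("a", "b"):
            block = ts.segment(seg)
            assert np.all(np.abs(block.mean(axis=2)) < 0.1)
            assert np.all(np.abs(block.std(axis=2) - 1.0) < 0.1)

    def test_annak_monotone_in_min_stress(self):
        # with beta > 0 the pair correlation grows with min(stress_i, stress_j)
        cfg = SyntheticConfig(
            n_subjects=30, run_lengths=(2000,), run_names=("v",), n_rois=1,
            base_shared_fraction=0.05, annak_coupling=0.5, seed=8,
        )
        stress = np.linspace(0, 1, 30)
        ts, _ = generate_timeseries(cfg, latent_stress=stress)
        r = np.corrcoef(ts.data[:, 0, :])
        iu = np.triu_indices(30, 1)
        min_s = np.minimum(stress[iu[0]], stress[iu[1]])
        low = r[iu][min_s < np.median(min_s)].mean()
        high = r[iu][min_s >= np.median(min_s)].mean()
        assert high > low

    def test_determinism_and_seed_sensitivity(self):
        cfg = SyntheticConfig(n_subjects=5, run_lengths=(50,), run_names=("v",),
                              n_rois=2, seed=11)
        a, _ = generate_timeseries(cfg)
        b, _ = generate_timeseries(cfg)
        assert np.array_equal(a.data, b.data)
        cfg2 = SyntheticConfig(n_subjects=5, run_lengths=(50,), run_names=("v",),
                               n_rois=2, seed=12)
        c, _ = generate_timeseries(cfg2)
        assert not np.array_equal(a.data, c.data)

    def test_weight_clipping_invariant(self):
        cfg = SyntheticConfig(n_subjects=10, run_lengths=(10,), run_names=("v",),
                              n_rois=3, base_shared_fraction=0.8,
                              annak_coupling=1.0, seed=0)
        w = effective_weights(cfg, np.linspace(-2, 2, 10))
        assert np.all(w >= 0) and np.all(w <= 0.95)

    def test_invalid_configs_rejected(self):
        with pytest.raises(ParameterError):
            SyntheticConfig(run_lengths=(2, 180, 180, 180))
        with pytest.raises(ParameterError):
            SyntheticConfig(base_shared_fraction=1.5)
        with pytest.raises(ParameterError):
            SyntheticConfig(ar1_coef=1.0)
        with pytest.raises(ParameterError):
            SyntheticConfig(annak_coupling=-0.1)


class TestFixtureIO:
    def _make(self, tmp_path, seed=13):
        cfg = SyntheticConfig(n_subjects=4, run_lengths=(20, 20),
                              run_names=("v1", "v2"), n_rois=2, seed=seed)
        ts, truth = generate_timeseries(cfg)
        behav = generate_behavioral_table(cfg, truth.latent_stress)
        return cfg, ts, behav, truth

    def test_round_trip(self, tmp_path):
        cfg, ts, behav, truth = self._make(tmp_path)
        write_fixture(ts, behav, truth, tmp_path / "fix", config=cfg)
        ts2, behav2, manifest = load_fixture(tmp_path / "fix")
        assert ts2.subjects == ts.subjects
        assert np.allclose(ts2.data, ts.data, atol=1e-9)
        assert behav2.equals(behav)
        assert manifest["seed"] == cfg.seed

    def test_regeneration_is_byte_identical(self, tmp_path):
        for d in ("a", "b"):
            cfg, ts, behav, truth = self._make(tmp_path)
            write_fixture(ts, behav, truth, tmp_path / d, config=cfg)
        ma = json.loads((tmp_path / "a" / "manifest.json").read_text())
        mb = json.loads((tmp_path / "b" / "manifest.json").read_text())
        assert ma["sha256"] == mb["sha256"]
        sub = ma["subjects"][0]
        assert (tmp_path / "a" / "timeseries" / f"{sub}.tsv").read_bytes() == \
               (tmp_path / "b" / "timeseries" / f"{sub}.tsv").read_bytes()

    def test_missing_parent_directory_fails_cleanly(self, tmp_path):
        cfg, ts, behav, truth = self._make(tmp_path)
        target = tmp_path / "no" / "such" / "dir"
        with pytest.raises(DataFormatError):
            write_fixture(ts, behav, truth, target, config=cfg)
        assert not target.exists()
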