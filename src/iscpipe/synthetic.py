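"""Synthetic subject x ROI x time ensembles with a known intersubject structure.

The generator emulates the statistical situation that intersubject
correlation (ISC) analysis assumes: every subject watching the same
stimulus carries a stimulus-locked *common* signal plus idiosyncratic
noise.  Subject ``i``'s series in ROI ``v`` during run ``r`` is

    x_i(t) = sqrt(w_i) * c(t) + sqrt(1 - w_i) * eps_i(t)

with ``c`` and ``eps_i`` independent, zero-mean, unit-variance processes
(optionally AR(1)-smoothed to mimic fMRI temporal autocorrelation).
Under this model the population Pearson correlation between subjects
``i`` and ``j`` is exactly ``sqrt(w_i * w_j)``, which gives every
downstream estimator a closed-form oracle.

An "Anna Karenina" coupling is available: a latent per-subject stress
trait raises the subject's shared-signal weight, ``w_i = clip(w0 +
beta * stress_norm_i, 0, 0.95)``, so that high-stress pairs are more
synchronized than low-stress pairs -- the structure that intersubject
representational similarity analysis (IS-RSA) is designed to detect.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.signal import lfilter
from scipy.stats import norm

from .errors import ParameterError, DataFormatError

__all__ = [
    "SyntheticConfig",
    "GroundTruth",
    "generate_stress_items",
    "generate_timeseries",
    "expected_pairwise_correlation",
    "write_fixture",
    "load_fixture",
]

#: Ceiling on any subject's shared-signal weight.  Keeps pairwise r away
#: from 1 so the Fisher z transform stays finite without relying on clipping.
WEIGHT_CEILING = 0.95


@dataclass
class SyntheticConfig:
    """Generative parameters for one synthetic dataset.

    Defaults mirror the emulated study design: 72 subjects, 16 ROIs,
    three ~3-minute ASMR runs plus one control run at TR = 1 s, with a
    modest shared-signal fraction and fMRI-like temporal smoothness.
    """

    n_subjects: int = 72
    run_lengths: tuple[int, ...] = (180, 180, 180, 180)
    run_names: tuple[str, ...] = ("video1", "video2", "video3", "control")
    n_rois: int = 16
    #: shared-signal fraction w0, one value per (ROI, run); scalars broadcast
    base_shared_fraction: float | np.ndarray = 0.1
    #: strength beta with which min-max-normalized stress raises w
    annak_coupling: float = 0.0
    ar1_coef: float = 0.3
    n_items: int = 6
    interitem_corr: float = 0.4
    tr: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_subjects < 2:
            raise ParameterError("n_subjects must be at least 2")
        if self.n_rois < 1:
            raise ParameterError("n_rois must be at least 1")
        if len(self.run_lengths) != len(self.run_names):
            raise ParameterError("run_lengths and run_names must align")
        if any(t < 3 for t in self.run_lengths):
            raise ParameterError("every run must have at least 3 time points")
        if not 0.0 <= self.ar1_coef < 1.0:
            raise ParameterError("ar1_coef must lie in [0, 1)")
        if self.annak_coupling < 0:
            raise ParameterError("annak_coupling must be >= 0")
        w0 = self.base_fraction_matrix()
        if np.any(w0 < 0) or np.any(w0 > 1):
            raise ParameterError("base_shared_fraction values must lie in [0, 1]")

    def base_fraction_matrix(self) -> np.ndarray:
        """Return w0 broadcast to shape (n_rois, n_runs)."""
        w0 = np.asarray(self.base_shared_fraction, dtype=float)
        return np.broadcast_to(w0, (self.n_rois, len(self.run_lengths))).copy()

    def to_dict(self) -> dict:
        d = asdict(self)
        d["base_shared_fraction"] = self.base_fraction_matrix().tolist()
        d["run_lengths"] = list(self.run_lengths)
        d["run_names"] = list(self.run_names)
        return d


@dataclass
class GroundTruth:
    """Latent quantities stored alongside every generated dataset."""

    latent_stress: np.ndarray  # (n_subjects,)
    effective_weight: np.ndarray  # (n_subjects, n_rois, n_runs)
    common_signals: np.ndarray  # (n_rois, n_runs, max_T), NaN-padded

    def to_jsonable(self) -> dict:
        return {
            "latent_stress": self.latent_stress.tolist(),
            "effective_weight": self.effective_weight.tolist(),
            "common_signals": np.where(
                np.isnan(self.common_signals), None, self.common_signals
            ).tolist(),
        }


def expected_pairwise_correlation(w_i: float, w_j: float) -> float:
    """Population Pearson correlation between two subjects' series.

    With unit-variance shared signal and noise the covariance between
    ``sqrt(w_i) c + sqrt(1-w_i) e_i`` and ``sqrt(w_j) c + sqrt(1-w_j) e_j``
    is ``sqrt(w_i w_j)`` and both variances are 1.
    """
    for name, w in (("w_i", w_i), ("w_j", w_j)):
        if not 0.0 <= w <= 1.0:
            raise ParameterError(f"{name} must lie in [0, 1], got {w}")
    return float(np.sqrt(w_i * w_j))


def _ar1(innovations: np.ndarray, phi: float) -> np.ndarray:
    """Filter white noise into a unit-variance AR(1) process along the last axis."""
    if phi == 0.0:
        return innovations
    out = lfilter([1.0], [1.0, -phi], innovations, axis=-1)
    # stationary variance of AR(1) driven by unit innovations is 1/(1-phi^2)
    return out * np.sqrt(1.0 - phi**2)


def generate_stress_items(
    n_subjects: int,
    n_items: int = 6,
    interitem_corr: float = 0.4,
    seed: int = 0,
) -> tuple[pd.DataFrame, np.ndarray]:
    """Simulate Likert stress items with a controllable inter-item correlation.

    A latent standard-normal trait ``s`` is shared across items:
    ``y_k = sqrt(rho) * s + sqrt(1-rho) * e_k``, then each ``y_k`` is cut at
    the equal-probability normal quantiles into the 5 Likert levels.  On
    the latent scale Cronbach's alpha follows the Spearman-Brown formula
    ``k rho / (1 + (k-1) rho)``; discretization attenuates the observed
    inter-item correlation by roughly 10%.

    Returns
    -------
    items : DataFrame of shape (n_subjects, n_items), integer values 1..5,
        columns ``item1..itemK``, index ``subject_id``.
    latent : the per-subject continuous trait (ground truth).
    """
    if n_items < 2:
        raise ParameterError("n_items must be at least 2")
    if not 0.0 <= interitem_corr < 1.0:
        raise ParameterError("interitem_corr must lie in [0, 1)")
    rng = np.random.default_rng(seed)
    latent = rng.standard_normal(n_subjects)
    noise = rng.standard_normal((n_subjects, n_items))
    y = np.sqrt(interitem_corr) * latent[:, None] + np.sqrt(1 - interitem_corr) * noise
    cuts = norm.ppf([0.2, 0.4, 0.6, 0.8])
    values = np.digitize(y, cuts) + 1  # integers 1..5
    items = pd.DataFrame(
        values,
        columns=[f"item{k + 1}" for k in range(n_items)],
        index=pd.Index([f"sub-{i + 1:03d}" for i in range(n_subjects)], name="subject_id"),
    )
    return items, latent


def _normalize_stress(latent_stress: np.ndarray) -> np.ndarray:
    """Min-max normalize the latent trait to [0, 1] over the sample."""
    lo, hi = latent_stress.min(), latent_stress.max()
    if hi == lo:
        return np.full_like(latent_stress, 0.5, dtype=float)
    return (latent_stress - lo) / (hi - lo)


def effective_weights(config: SyntheticConfig, latent_stress: np.ndarray) -> np.ndarray:
    """Per-subject shared-signal weights w_i = clip(w0 + beta * s_norm, 0, 0.95)."""
    s = _normalize_stress(np.asarray(latent_stress, dtype=float))
    w0 = config.base_fraction_matrix()  # (R, V)
    w = w0[None, :, :] + config.annak_coupling * s[:, None, None]
    return np.clip(w, 0.0, WEIGHT_CEILING)


def generate_timeseries(
    config: SyntheticConfig,
    latent_stress: np.ndarray | None = None,
):
    """Generate a SubjectTimeseriesSet plus its GroundTruth.

    Each ROI x run gets one common signal shared by all subjects; each
    subject adds independent noise.  Both processes are AR(1) with
    ``config.ar1_coef`` and unit stationary variance, so the population
    correlation between subjects i and j is ``sqrt(w_i w_j)`` exactly.
    Identical (config, latent_stress) and seed give identical output.
    """
    from .isc import SubjectTimeseriesSet  # avoid circular import at module load

    if latent_stress is None:
        rng_trait = np.random.default_rng(config.seed + 1_000_003)
        latent_stress = rng_trait.standard_normal(config.n_subjects)
    latent_stress = np.asarray(latent_stress, dtype=float)
    if latent_stress.shape != (config.n_subjects,):
        raise ParameterError(
            f"latent_stress must have length n_subjects={config.n_subjects}"
        )

    n, R = config.n_subjects, config.n_rois
    lengths = config.run_lengths
    V = len(lengths)
    total_T = int(sum(lengths))
    max_T = int(max(lengths))

    w = effective_weights(config, latent_stress)  # (n, R, V)
    rng = np.random.default_rng(config.seed)

    common = np.full((R, V, max_T), np.nan)
    data = np.empty((n, R, total_T))
    offsets = np.cumsum([0, *lengths])
    for v, T in enumerate(lengths):
        c = _ar1(rng.standard_normal((R, T)), config.ar1_coef)  # (R, T)
        common[:, v, :T] = c
        eps = _ar1(rng.standard_normal((n, R, T)), config.ar1_coef)
        amp = np.sqrt(w[:, :, v])[:, :, None]
        data[:, :, offsets[v]:offsets[v + 1]] = amp * c[None] + np.sqrt(1 - amp**2) * eps

    subjects = [f"sub-{i + 1:03d}" for i in range(n)]
    roi_labels = [f"roi{r + 1:02d}" for r in range(R)]
    runs = {
        name: (int(offsets[v]), int(lengths[v]))
        for v, name in enumerate(config.run_names)
    }
    ts = SubjectTimeseriesSet(
        subjects=subjects, roi_labels=roi_labels, data=data, runs=runs, tr=config.tr
    )
    truth = GroundTruth(
        latent_stress=latent_stress, effective_weight=w, common_signals=common
    )
    return ts, truth


def generate_behavioral_table(
    config: SyntheticConfig, latent_stress: np.ndarray, seed: int | None = None
) -> pd.DataFrame:
    """Full behavioral CSV contents: stress items + viewing habits + flags.

    Items are regenerated from the *given* latent trait (so the neural
    AnnaK coupling and the questionnaire share one ground truth).  ASMR
    viewing frequency, willingness and per-channel familiarity are drawn
    independently of stress, matching the emulated study's report of no
    significant relationship between behavioral measures.
    """
    rng = np.random.default_rng(config.seed + 7 if seed is None else seed)
    n, k = config.n_subjects, config.n_items
    noise = rng.standard_normal((n, k))
    rho = config.interitem_corr
    z = (latent_stress - latent_stress.mean()) / (latent_stress.std() or 1.0)
    y = np.sqrt(rho) * z[:, None] + np.sqrt(1 - rho) * noise
    cuts = norm.ppf([0.2, 0.4, 0.6, 0.8])
    items = np.digitize(y, cuts) + 1

    # frequency skewed low (the emulated sample rarely watched ASMR)
    freq = rng.choice([1, 2, 3, 4, 5], size=n, p=[0.65, 0.15, 0.1, 0.06, 0.04])
    willing = rng.integers(0, 2, size=n)
    familiar = rng.binomial(1, [0.7, 0.1, 0.05], size=(n, 3))

    table = pd.DataFrame(
        {f"item{j + 1}": items[:, j] for j in range(k)},
        index=pd.Index([f"sub-{i + 1:03d}" for i in range(n)], name="subject_id"),
    )
    table["freq"] = freq
    table["willing"] = willing
    for c in range(3):
        table[f"familiar_ch{c + 1}"] = familiar[:, c]
    return table


def write_fixture(
    dataset,
    behavioral: pd.DataFrame,
    truth: GroundTruth,
    directory: str | Path,
    config: SyntheticConfig | None = None,
) -> Path:
    """Write a complete on-disk fixture and return the manifest path.

    Layout: one TSV per subject (rows = time points, columns = ROI labels,
    header mandatory), ``behavioral.csv``, ``ground_truth.json`` and a
    ``manifest.json`` recording the seed, config, run structure and a
    content hash.  The parent directory must already exist; nothing is
    written if it does not (atomicity at the directory level).
    """
    directory = Path(directory)
    if not directory.parent.exists():
        raise DataFormatError(f"parent directory does not exist: {directory.parent}")
    directory.mkdir(exist_ok=True)

    ts_dir = directory / "timeseries"
    ts_dir.mkdir(exist_ok=True)
    digest = hashlib.sha256()
    for i, sub in enumerate(dataset.subjects):
        frame = pd.DataFrame(dataset.data[i].T, columns=dataset.roi_labels)
        path = ts_dir / f"{sub}.tsv"
        frame.to_csv(path, sep="\t", index=False, float_format="%.10g")
        digest.update(path.read_bytes())

    behavioral.to_csv(directory / "behavioral.csv")
    digest.update((directory / "behavioral.csv").read_bytes())

    (directory / "ground_truth.json").write_text(
        json.dumps(truth.to_jsonable(), indent=1)
    )

    manifest = {
        "seed": None if config is None else config.seed,
        "config": None if config is None else config.to_dict(),
        "subjects": list(dataset.subjects),
        "roi_labels": list(dataset.roi_labels),
        "runs": {k: list(v) for k, v in dataset.runs.items()},
        "tr": dataset.tr,
        "sha256": digest.hexdigest(),
    }
    manifest_path = directory / "manifest.json"
    manifest_path.write_text(json.dumps(manifest, indent=1))
    return manifest_path


def load_fixture(directory: str | Path):
    """Read a fixture written by :func:`write_fixture`.

    Returns ``(SubjectTimeseriesSet, behavioral DataFrame, manifest dict)``.
    """
    from .isc import SubjectTimeseriesSet

    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        raise DataFormatError(f"no manifest.json under {directory}")
    manifest = json.loads(manifest_path.read_text())
    subjects = manifest["subjects"]
    roi_labels = manifest["roi_labels"]
    arrays = []
    for sub in subjects:
        frame = pd.read_csv(directory / "timeseries" / f"{sub}.tsv", sep="\t")
        if list(frame.columns) != roi_labels:
            raise DataFormatError(f"ROI columns for {sub} do not match the manifest")
        arrays.append(frame.to_numpy().T)
    data = np.stack(arrays)
    runs = {k: (int(a), int(b)) for k, (a, b) in manifest["runs"].items()}
    ts = SubjectTimeseriesSet(
        subjects=subjects, roi_labels=roi_labels, data=data,
        runs=runs, tr=float(manifest["tr"]),
    )
    behavioral = pd.read_csv(directory / "behavioral.csv", index_col="subject_id")
    return ts, behavioral, manifest
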