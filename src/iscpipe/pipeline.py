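"""Config-driven orchestration of the full ISC / IS-RSA battery.

``run_pipeline`` executes, in order: load or simulate data; per-video
pairwise ISC; Friedman omnibus across videos with Wilcoxon post hocs
and FDR; ISC on the concatenated ASMR session with subject-wise
bootstrap and FDR; stress IS-RSA per video and concatenated; control
(non-ASMR) IS-RSA with paired-t profile contrasts; group ISC
comparisons (willingness, channel familiarity); viewing-frequency
IS-RSA; and a behavioral summary.  Everything is deterministic given
the config and its seed, and every randomized result records the seed
and iteration count it used.
"""

from __future__ import annotations

import contextlib
import json
import logging
import time
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__ as _pkg_version
from .behavioral import (
    annak_similarity,
    describe_sample,
    frequency_similarity,
    score_stress,
)
from .errors import IscPipeError, ParameterError, ValidationError
from .isc import (
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
from .isrsa import isrsa_battery, mantel_permutation_test, paired_t_profile
from .synthetic import (
    SyntheticConfig,
    generate_behavioral_table,
    generate_timeseries,
    load_fixture,
    write_fixture,
)

logger = logging.getLogger("iscpipe")

__all__ = ["AnalysisConfig", "ReportBundle", "run_pipeline", "validate_inputs"]


@dataclass
class AnalysisConfig:
    """Resolved pipeline configuration (flat keys, YAML-loadable)."""

    mode: str = "synthetic"  # "synthetic" | "files"
    data_dir: str | None = None  # fixture directory in files mode
    roi_labels: list[str] | None = None  # optional subset/order of ROI columns
    video_segments: list[str] = field(default_factory=lambda: ["video1", "video2", "video3"])
    control_segment: str | None = "control"
    annak_variant: str = "annak_mean"
    reverse_keys: list[int] = field(default_factory=list)
    summary: str = "mean_z"
    n_bootstrap: int = 5000
    n_permutations: int = 5000
    alpha: float = 0.05
    seed: int = 0
    out_dir: str | None = None
    synthetic: dict = field(default_factory=dict)  # SyntheticConfig overrides

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "files"):
            raise ParameterError("mode must be 'synthetic' or 'files'")
        if not 0.0 < self.alpha < 1.0:
            raise ParameterError("alpha must lie in (0, 1)")
        if self.mode == "files" and not self.data_dir:
            raise ParameterError("files mode requires data_dir")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "AnalysisConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class ReportBundle:
    """All result tables from one pipeline run, plus the run manifest."""

    isc_table: pd.DataFrame  # Table-1 shape: per-ROI concatenated ISC + p/q
    friedman_table: pd.DataFrame  # per-ROI cross-video omnibus
    posthoc_table: pd.DataFrame  # Wilcoxon pairs for significant ROIs
    isrsa_table: pd.DataFrame  # per ROI x condition stress IS-RSA
    contrast_table: pd.DataFrame  # paired-t: each video profile vs control
    group_table: pd.DataFrame  # willingness / familiarity ISC differences
    freq_isrsa_table: pd.DataFrame  # viewing-frequency IS-RSA
    behavioral_summary: dict
    pairwise_long: pd.DataFrame  # box-plot-ready pairwise values
    manifest: dict

    def write(self, out_dir: str | Path) -> Path:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        tables = {
            "isc_concatenated.tsv": self.isc_table,
            "friedman_cross_video.tsv": self.friedman_table,
            "wilcoxon_posthoc.tsv": self.posthoc_table,
            "isrsa_stress.tsv": self.isrsa_table,
            "isrsa_contrasts.tsv": self.contrast_table,
            "group_isc.tsv": self.group_table,
            "isrsa_frequency.tsv": self.freq_isrsa_table,
        }
        for name, frame in tables.items():
            frame.to_csv(out / name, sep="\t", index=False, float_format="%.6g")
        self.pairwise_long.to_csv(out / "pairwise_long.csv", index=False,
                                  float_format="%.6g")
        (out / "behavioral_summary.json").write_text(
            json.dumps(self.behavioral_summary, indent=1)
        )
        (out / "manifest.json").write_text(json.dumps(self.manifest, indent=1))
        return out / "manifest.json"


@contextlib.contextmanager
def _stage(name: str):
    t0 = time.perf_counter()
    logger.info("stage %s: start", name)
    try:
        yield
    except IscPipeError as exc:
        raise IscPipeError(f"stage '{name}' failed: {exc}") from exc
    logger.info("stage %s: done in %.2fs", name, time.perf_counter() - t0)


def _load_or_simulate(config: AnalysisConfig):
    if config.mode == "synthetic":
        syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
        ts, truth = generate_timeseries(syn)
        behavioral = generate_behavioral_table(syn, truth.latent_stress)
        return ts, behavioral, syn
    ts, behavioral, _manifest = load_fixture(config.data_dir)
    return ts, behavioral, None


def _roi_matrices(
    ts: SubjectTimeseriesSet, segment: str | None, condition: str
) -> dict[str, PairwiseIscMatrix]:
    """Pairwise ISC per ROI for one named segment (None = whole data)."""
    block = ts.segment(segment) if segment is not None else ts.data
    out = {}
    for r, roi in enumerate(ts.roi_labels):
        out[roi] = pairwise_isc(
            block[:, r, :], subjects=ts.subjects, roi=roi, condition=condition
        )
    return out


def _subset_ts(ts: SubjectTimeseriesSet, keep: list[str]) -> SubjectTimeseriesSet:
    idx = [ts.subjects.index(s) for s in keep]
    return SubjectTimeseriesSet(
        subjects=keep, roi_labels=list(ts.roi_labels),
        data=ts.data[idx], runs=dict(ts.runs), tr=ts.tr,
    )


def run_pipeline(config: AnalysisConfig) -> ReportBundle:
    """Execute the full analysis battery; deterministic given config + seed."""
    rng_base = int(config.seed) % (2**31)

    with _stage("load"):
        ts, behavioral, syn = _load_or_simulate(config)
        missing_segments = [
            s for s in [*config.video_segments,
                        *([config.control_segment] if config.control_segment else [])]
            if s not in ts.runs
        ]
        if missing_segments:
            raise ValidationError(f"segments not present in data: {missing_segments}")

    with _stage("per_video_isc"):
        per_video = {
            seg: _roi_matrices(ts, seg, seg) for seg in config.video_segments
        }

    with _stage("friedman_posthoc"):
        fried_rows = []
        for roi in ts.roi_labels:
            chi2, df, p = friedman_across_conditions(
                [per_video[seg][roi] for seg in config.video_segments]
            )
            fried_rows.append({"roi": roi, "chi2": chi2, "df": df, "p": p})
        friedman_table = pd.DataFrame(fried_rows)
        friedman_table["q"] = bh_fdr(friedman_table["p"])
        friedman_table["n_pairs"] = ts.n_subjects * (ts.n_subjects - 1) // 2

        posthoc_rows = []
        sig_rois = friedman_table.loc[friedman_table["q"] < config.alpha, "roi"]
        segs = config.video_segments
        for roi in sig_rois:
            for a in range(len(segs)):
                for b in range(a + 1, len(segs)):
                    tri_a = per_video[segs[a]][roi].triangle()
                    tri_b = per_video[segs[b]][roi].triangle()
                    W, zstat, p = wilcoxon_signed_rank(tri_a, tri_b)
                    posthoc_rows.append(
                        {"roi": roi, "video_a": segs[a], "video_b": segs[b],
                         "W": W, "z": zstat, "p": p,
                         "mean_z_a": float(np.mean(tri_a)),
                         "mean_z_b": float(np.mean(tri_b))}
                    )
        posthoc_table = pd.DataFrame(
            posthoc_rows,
            columns=["roi", "video_a", "video_b", "W", "z", "p",
                     "mean_z_a", "mean_z_b"],
        )
        if len(posthoc_table):
            posthoc_table["q"] = bh_fdr(posthoc_table["p"])
        else:
            posthoc_table["q"] = pd.Series(dtype=float)

    with _stage("concatenated_isc_bootstrap"):
        concat = concatenate_runs(ts, config.video_segments, name="concat")
        concat_mats = _roi_matrices(concat, "concat", "concat")
        isc_rows = []
        for r_idx, roi in enumerate(ts.roi_labels):
            res = bootstrap_isc_test(
                concat_mats[roi],
                n_iterations=config.n_bootstrap,
                seed=(rng_base + 811 * r_idx) % (2**31),
                summary=config.summary,
            )
            isc_rows.append(
                {"roi": roi, "isc": res.observed_isc, "p": res.p,
                 "n_iterations": res.n_iterations, "seed": res.seed}
            )
        isc_table = pd.DataFrame(isc_rows)
        isc_table["q"] = bh_fdr(isc_table["p"])
        isc_table = isc_table[["roi", "isc", "p", "q", "n_iterations", "seed"]]

    with _stage("behavioral"):
        item_cols = [c for c in behavioral.columns if c.startswith("item")]
        complete = behavioral.dropna(subset=item_cols)
        complete = complete[complete.index.isin(ts.subjects)]
        kept = [s for s in ts.subjects if s in complete.index]
        stress = score_stress(
            complete.loc[kept, item_cols].to_numpy(), set(config.reverse_keys)
        )
        behav_summary = describe_sample(behavioral, set(config.reverse_keys))
        behav_summary["n_complete_items"] = len(kept)
        stress_sim = annak_similarity(
            stress, variant=config.annak_variant, subjects=kept
        )

    with _stage("stress_isrsa"):
        ts_b = _subset_ts(ts, kept) if kept != ts.subjects else ts
        concat_b = concatenate_runs(ts_b, config.video_segments, name="concat")
        isrsa_input = {
            seg: _roi_matrices(ts_b, seg, seg) for seg in config.video_segments
        }
        isrsa_input["concat"] = _roi_matrices(concat_b, "concat", "concat")
        isrsa_results = isrsa_battery(
            isrsa_input, stress_sim,
            n_permutations=config.n_permutations, seed=rng_base,
        )
        isrsa_table = pd.DataFrame(
            [{"roi": r.roi, "condition": r.condition, "rho": r.rho,
              "p": r.p, "q": r.q, "n_permutations": r.n_permutations,
              "seed": r.seed} for r in isrsa_results]
        )

    with _stage("control_contrast"):
        contrast_rows = []
        if config.control_segment:
            control_mats = _roi_matrices(
                ts_b, config.control_segment, config.control_segment
            )
            control_rhos = {}
            for r_idx, roi in enumerate(ts.roi_labels):
                rho, p = mantel_permutation_test(
                    control_mats[roi], stress_sim,
                    n_permutations=config.n_permutations,
                    seed=(rng_base + 37_199 + r_idx) % (2**31),
                )
                control_rhos[roi] = rho
            ctrl_profile = [control_rhos[roi] for roi in ts.roi_labels]
            for seg in config.video_segments:
                seg_rows = isrsa_table[isrsa_table["condition"] == seg]
                seg_rows = seg_rows.set_index("roi")["rho"]
                seg_profile = [float(seg_rows[roi]) for roi in ts.roi_labels]
                t, df, p = paired_t_profile(seg_profile, ctrl_profile)
                contrast_rows.append(
                    {"video": seg, "control": config.control_segment,
                     "t": t, "df": df, "p": p}
                )
        contrast_table = pd.DataFrame(
            contrast_rows, columns=["video", "control", "t", "df", "p"]
        )

    with _stage("group_isc"):
        group_rows = []
        flag_cols = [c for c in behavioral.columns
                     if c == "willing" or c.startswith("familiar")]
        for f_idx, flag in enumerate(flag_cols):
            labels = behavioral.reindex(ts.subjects)[flag].to_numpy()
            if np.any(pd.isna(labels)):
                group_rows.append({"grouping": flag, "roi": "", "diff": np.nan,
                                   "p": np.nan, "note": "missing labels; skipped"})
                continue
            labels = labels.astype(bool)
            if labels.sum() < 3 or (~labels).sum() < 3:
                group_rows.append(
                    {"grouping": flag, "roi": "", "diff": np.nan, "p": np.nan,
                     "note": f"group sizes {int(labels.sum())}/"
                             f"{int((~labels).sum())} too small; skipped"}
                )
                continue
            for r_idx, roi in enumerate(ts.roi_labels):
                diff, p = group_isc_difference(
                    concat.segment("concat")[:, r_idx, :], labels,
                    n_permutations=config.n_permutations,
                    seed=(rng_base + 61_001 + 257 * f_idx + r_idx) % (2**31),
                    subjects=ts.subjects, roi=roi, condition="concat",
                )
                group_rows.append({"grouping": flag, "roi": roi,
                                   "diff": diff, "p": p, "note": ""})
        group_table = pd.DataFrame(
            group_rows, columns=["grouping", "roi", "diff", "p", "note"]
        )
        tested = group_table["note"] == ""
        group_table["q"] = np.nan
        for flag in group_table.loc[tested, "grouping"].unique():
            sel = tested & (group_table["grouping"] == flag)
            group_table.loc[sel, "q"] = bh_fdr(group_table.loc[sel, "p"])

    with _stage("frequency_isrsa"):
        freq_rows = []
        freqs = behavioral.reindex(kept)["freq"] if "freq" in behavioral else None
        if freqs is not None and freqs.notna().all() and freqs.nunique() > 1:
            freq_sim = frequency_similarity(
                freqs.to_numpy(), variant=config.annak_variant, subjects=kept
            )
            for r_idx, roi in enumerate(ts.roi_labels):
                rho, p = mantel_permutation_test(
                    isrsa_input["concat"][roi], freq_sim,
                    n_permutations=config.n_permutations,
                    seed=(rng_base + 90_017 + r_idx) % (2**31),
                )
                freq_rows.append({"roi": roi, "rho": rho, "p": p})
        freq_isrsa_table = pd.DataFrame(freq_rows, columns=["roi", "rho", "p"])
        if len(freq_isrsa_table):
            freq_isrsa_table["q"] = bh_fdr(freq_isrsa_table["p"])
        else:
            freq_isrsa_table["q"] = pd.Series(dtype=float)

    with _stage("report"):
        long_rows = []
        all_conditions = {**per_video}
        if config.control_segment:
            all_conditions[config.control_segment] = _roi_matrices(
                ts, config.control_segment, config.control_segment
            )
        all_conditions["concat"] = concat_mats
        for cond, mats in all_conditions.items():
            for roi, m in mats.items():
                tri = m.triangle()
                long_rows.append(pd.DataFrame({
                    "condition": cond, "roi": roi,
                    "pair_index": np.arange(tri.size), "z": tri,
                }))
        pairwise_long = pd.concat(long_rows, ignore_index=True)

        manifest = {
            "iscpipe_version": _pkg_version,
            "config": config.to_dict(),
            "synthetic_config": None if syn is None else syn.to_dict(),
            "n_subjects": ts.n_subjects,
            "n_rois": ts.n_rois,
            "subjects": list(ts.subjects),
            "roi_labels": list(ts.roi_labels),
            "seed": config.seed,
            "multiple_testing": {
                "family": "ROIs within each analysis",
                "method": "benjamini-hochberg",
            },
            "caveats": [
                "Friedman/Wilcoxon observation unit is the subject pair; "
                "pairs sharing a subject are dependent.",
            ],
        }

    bundle = ReportBundle(
        isc_table=isc_table,
        friedman_table=friedman_table,
        posthoc_table=posthoc_table,
        isrsa_table=isrsa_table,
        contrast_table=contrast_table,
        group_table=group_table,
        freq_isrsa_table=freq_isrsa_table,
        behavioral_summary=behav_summary,
        pairwise_long=pairwise_long,
        manifest=manifest,
    )
    if config.out_dir:
        bundle.write(config.out_dir)
    return bundle


def simulate_to_directory(config: AnalysisConfig, directory: str | Path) -> Path:
    """Generate a synthetic dataset per the config and write it as a fixture."""
    syn = SyntheticConfig(**{"seed": config.seed, **config.synthetic})
    ts, truth = generate_timeseries(syn)
    behavioral = generate_behavioral_table(syn, truth.latent_stress)
    return write_fixture(ts, behavioral, truth, directory, config=syn)


def validate_inputs(directory: str | Path) -> list[str]:
    """Check an on-disk fixture for consistency; returns ALL problems found.

    Report-only: an empty list means the fixture is analyzable.
    """
    problems: list[str] = []
    directory = Path(directory)
    manifest_path = directory / "manifest.json"
    if not manifest_path.exists():
        return [f"missing manifest.json in {directory}"]
    try:
        manifest = json.loads(manifest_path.read_text())
    except json.JSONDecodeError as exc:
        return [f"unreadable manifest.json: {exc}"]

    subjects = manifest.get("subjects", [])
    roi_labels = manifest.get("roi_labels", [])
    runs = manifest.get("runs", {})
    expected_T = None
    for sub in subjects:
        path = directory / "timeseries" / f"{sub}.tsv"
        if not path.exists():
            problems.append(f"missing time-series file for {sub}")
            continue
        frame = pd.read_csv(path, sep="\t")
        if list(frame.columns) != roi_labels:
            problems.append(f"{sub}: ROI columns differ from manifest")
        if expected_T is None:
            expected_T = len(frame)
        elif len(frame) != expected_T:
            problems.append(
                f"{sub}: {len(frame)} time points, expected {expected_T}"
            )
        if frame.isna().any().any():
            problems.append(f"{sub}: NaN values in time series")
    if expected_T is not None:
        for name, (start, length) in runs.items():
            if start < 0 or start + length > expected_T:
                problems.append(
                    f"run '{name}' ({start}+{length}) exceeds {expected_T} samples"
                )

    behav_path = directory / "behavioral.csv"
    if not behav_path.exists():
        problems.append("missing behavioral.csv")
        return problems
    behavioral = pd.read_csv(behav_path, index_col="subject_id")
    missing = [s for s in subjects if s not in behavioral.index]
    for s in missing:
        problems.append(f"behavioral.csv missing subject {s}")
    item_cols = [c for c in behavioral.columns if c.startswith("item")]
    items = behavioral[item_cols]
    bad = items[(items < 1) | (items > 5)].dropna(how="all")
    for s in bad.index:
        problems.append(f"behavioral.csv: out-of-range item values for {s}")
    return problems
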