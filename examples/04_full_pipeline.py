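"""Run the complete analysis battery on a synthetic study and print the
report tables it writes.

The emulated design: 3 videos plus 1 control run, pairwise ISC per
video, Friedman/Wilcoxon cross-video comparison, bootstrap inference on
the concatenated session, stress and viewing-frequency IS-RSA, group
comparisons, and a behavioral summary.  (Small sizes here keep the
example quick; defaults emulate 72 subjects x 16 ROIs x 180-s runs.)
"""

from iscpipe.pipeline import AnalysisConfig, run_pipeline

cfg = AnalysisConfig(
    mode="synthetic",
    seed=1,
    n_bootstrap=500,
    n_permutations=500,
    synthetic=dict(
        n_subjects=16,
        n_rois=4,
        run_lengths=(90, 90, 90, 90),
        base_shared_fraction=0.15,
        annak_coupling=0.2,
    ),
    out_dir="scratch/pipeline_demo",
)
bundle = run_pipeline(cfg)

print("concatenated-session ISC per ROI (Table-1-shaped):")
print(bundle.isc_table[["roi", "isc", "p", "q"]].to_string(index=False))
print("\ncross-video Friedman omnibus:")
print(bundle.friedman_table[["roi", "chi2", "p", "q"]].to_string(index=False))
print("\nstress IS-RSA (concatenated condition):")
sel = bundle.isrsa_table.query("condition == 'concat'")
print(sel[["roi", "rho", "p", "q"]].to_string(index=False))
print("\nbehavioral summary:", bundle.behavioral_summary["composite_stress"])
print("\nAll tables were also written under scratch/pipeline_demo/.")
print("With w = 0.15 everywhere the ISC column sits near 0.15 and q < 0.05;")
print("the mild AnnaK coupling may or may not reach significance at n = 16.")
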