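"""Run the two-stage analysis end to end on a synthetic cohort.

Stage 1 finds amplitude-abnormal ROIs per band via fALFF + RFE + top-N
sweep; stage 2 extracts sliding-window connectivity among them and reports
grid-searched SVM classification per (scheme, window width).  Sizes are
reduced so the example finishes in about a minute.
"""

from pathlib import Path

from mfdfc import CohortSpec
from mfdfc.pipeline import PipelineConfig, run_all

spec = CohortSpec(
    n_per_group=12,
    n_rois=10,
    noise_sd=0.3,
    subject_amplitude_sd=0.1,
    seed=5,
    falff_effects=((2, "Slow-5", 2.0), (5, "Slow-4", 2.0), (7, "Slow-4", 2.0)),
    dfc_effects=((5, 7, "Slow-4", 0.8, 0.0),),
)
config = PipelineConfig(
    cohort_spec=spec,
    schemes=("Conventional", "Combined"),
    window_widths=(15, 20),
    n_repeats=2,
    sweep_n_max=8,
    rank_cv_folds=2,
    rank_step_fraction=0.25,
    cv_folds=4,
    seed=5,
    output_dir="pipeline_example_out",
)

manifest = run_all(config)
outdir = Path(config.output_dir)
print(f"artifacts written to {outdir}/ (band table, rankings, accuracy curves,")
print("pair-count tables and heatmaps, per-combination reports, manifest.json)")
print()
print((outdir / "dfc_summary.tsv").read_text().rstrip())
print()
print("rows are (scheme, window width); AUC/ACC near 1 reflect the strong")
print("injected effects; the manifest allows a bit-identical re-run")
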