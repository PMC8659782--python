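"""Run the end-to-end pipeline: synthesize, extract, select, tune, classify.

One call to run_pipeline executes every stage with per-stage sub-seeds
derived from the master seed, so the printed report is fully reproducible.
A modest scale (20 per grade, small GWO budget) keeps this example fast;
the acceptance script runs the same pipeline at 100 per grade.
"""

from notoroot import PipelineConfig, TuneConfig, run_pipeline

config = PipelineConfig(
    n_per_grade=20,
    selection="iriv",
    tuner="gwo",
    tune=TuneConfig(pop=8, iters=15),
    seed=1,
)
report = run_pipeline(config)

print(f"features before selection: {report.n_features_before}")
print(f"features after IRIV:       {report.n_features_after}")
print(f"selected: {report.selected}")
print(f"tuned (c, g): ({report.tuned_c:.3f}, {report.tuned_g:.4f})")
print(f"train accuracy: {report.train_report['accuracy_pct']:.2f}%")
print(f"test accuracy:  {report.test_report['accuracy_pct']:.2f}%")
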