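"""Run the complete pipeline on a tiny synthetic cohort.

Simulates lumbar + abdominal CT for 2 development patients and 1 test
patient, reformats all disc levels, trains the dual-decoder U-Net
briefly, segments the test slices, measures DSAs, classifies stenosis
and prints the stratified evaluation report.  Artifacts (manifest,
measurements, metrics tables) land under scratch/example_run/.
"""

from canalseg import RunConfig, run_pipeline

config = RunConfig(
    out_dir="scratch/example_run",
    n_dev_patients=2,
    n_test_patients=1,
    epochs=4,
    seed=1,
)
report = run_pipeline(config)

print(report.render())
print("\nRows stratify the test set overall / per acquisition mode; "
      "'Level (narrowest)' applies the narrowest-slice rule before "
      "classifying.  With minutes of CPU training the DSC is modest; "
      "longer schedules push it toward the ~0.9 the recovery "
      "experiment reaches.")
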