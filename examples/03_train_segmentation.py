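"""Train the dual-decoder U-Net on phantom slices (scaled-down demo).

Draws labelled and unlabelled canal-centred slices from one phantom
patient, trains the single-encoder / dual-decoder network with
cross-entropy plus the L2 cross-decoder consistency loss, and reports
held-out Dice.  Runs in a few minutes on one CPU; raise the sizes for
the full experiment (160 x 160, 40 labelled + 160 unlabelled, 50
epochs).
"""

from canalseg.experiments import dsc_recovery_experiment

result = dsc_recovery_experiment(
    seed=1,
    consistency_weight=1.0,
    n_labeled=20,
    n_unlabeled=40,
    n_heldout=12,
    input_px=64,
    epochs=15,
    n_patients=1,
)

print(f"labelled slices   : {result.n_labeled}")
print(f"unlabelled slices : {result.n_unlabeled}")
print(f"epochs            : {result.epochs}")
print(f"held-out mean DSC : {result.heldout_dsc:.3f}")
print("\nA held-out Dice above 0.8 on this high-contrast task shows the "
      "semi-supervised loop optimises dural-sac overlap as intended.")
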