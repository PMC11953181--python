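"""End-to-end phantom pipeline: simulate -> reformat -> train -> infer
-> classify -> evaluate.

Every run is a pure function of (config, seed): one root seed is split
per stage, artifacts land under the output directory, and re-running
with the same configuration reproduces the evaluation tables byte for
byte.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import io
from .core import CTVolume, LabelVolume
from .dataset import build_manifest, manifest_counts
from .evaluation import EvalReport, dice, evaluate_testset
from .geometry import ReformatSpec, disc_centers, fit_spinal_curve, locate_centroids, reformat_level
from .nn import DualDecoderUNet, DualDecoderUNetConfig
from .phantom import _BODY_ANTERIOR_OFFSET, apply_acquisition_mode, generate_phantom, sample_config
from .stenosis import dsa_from_mask
from .training import AugmentParams, TrainingConfig, predict_mask, train


@dataclass(frozen=True)
class RunConfig:
    """One configuration drives a complete run."""

    out_dir: str
    n_dev_patients: int = 2
    n_test_patients: int = 1
    epochs: int = 2
    batch_size: int = 8
    consistency_weight: float = 1.0
    augment: bool = False
    input_px: int = 64          # model input side; window = input_px * pixel_mm
    pixel_mm: float = 0.5
    noise_sd_hu: float = 5.0
    base_channels: int = 16
    depth: int = 4
    seed: int = 0
    save_volumes: bool = True

    def __post_init__(self) -> None:
        if self.n_dev_patients < 1:
            raise ValueError("need at least one development patient (no labelled training data otherwise)")
        if self.n_test_patients < 1:
            raise ValueError("need at least one test patient")


@dataclass
class PatientData:
    """Reformatted stacks for one patient, keyed (mode, level)."""

    patient_id: str
    stacks: dict = field(default_factory=dict)
    truth: object = None


def _reformat_patient(
    pid: str,
    volumes: dict[str, CTVolume],
    labels: LabelVolume,
    spec: ReformatSpec,
) -> PatientData:
    data = PatientData(pid)
    for mode, vol in volumes.items():
        cents = locate_centroids(vol)
        # anchor the curve on the canal axis (a known, fixed distance
        # posterior to the vertebral-body centroids in the phantom), so
        # reformat planes are centred on the dural sac itself
        cents = cents - np.array([0.0, _BODY_ANTERIOR_OFFSET, 0.0])
        curve = fit_spinal_curve(cents)
        dcs = disc_centers(curve, cents)
        s_mid = (curve.control_arclengths[:-1] + curve.control_arclengths[1:]) / 2.0
        from .core import LEVELS
        for j in range(len(dcs)):
            stack = reformat_level(vol, curve, float(s_mid[j]), level=LEVELS[j],
                                   labels=labels, spec=spec)
            data.stacks[(mode, LEVELS[j])] = stack
    return data


def run_pipeline(config: RunConfig) -> EvalReport:
    """Execute all stages; returns the evaluation report.

    Writes under ``out_dir``: phantom volumes (NIfTI), the dataset
    manifest, per-slice measurements, training history and the
    evaluation tables (CSV plus a plain-text rendering).
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    seeds = {name: int(s.generate_state(1)[0] % (2**31))
             for name, s in zip(("phantom", "manifest", "train"), root.spawn(3))}
    rng_phantom = np.random.default_rng(seeds["phantom"])

    spec = ReformatSpec(
        fov_mm=config.input_px * config.pixel_mm,
        pixel_spacing_mm=config.pixel_mm,
    )

    dev_ids = [f"dev{i:03d}" for i in range(config.n_dev_patients)]
    test_ids = [f"test{i:03d}" for i in range(config.n_test_patients)]

    # --- simulate + reformat ------------------------------------------
    patients: dict[str, PatientData] = {}
    truth_rows = []
    for pid in dev_ids + test_ids:
        pcfg = sample_config(rng_phantom, noise_sd_hu=config.noise_sd_hu,
                             seed=int(rng_phantom.integers(2**31)))
        vol, lab, gt = generate_phantom(pcfg)
        vol = dataclasses.replace(vol, patient_id=pid)
        modes = {
            m: apply_acquisition_mode(vol, lab, m, config.noise_sd_hu,
                                      seed=int(rng_phantom.integers(2**31)))
            for m in ("lumbar", "abdominal")
        }
        for m in modes:
            modes[m] = dataclasses.replace(modes[m], patient_id=pid)
        if config.save_volumes:
            vdir = out / "volumes"
            vdir.mkdir(exist_ok=True)
            for m, v in modes.items():
                io.write_volume(v, vdir / f"{pid}_{m}.nii.gz")
            io.write_labels(lab, vdir / f"{pid}_labels.nii.gz")
        pdata = _reformat_patient(pid, modes, lab, spec)
        pdata.truth = gt
        patients[pid] = pdata
        for (lv, off), a in gt.dsa_profile.items():
            truth_rows.append({"patient_id": pid, "level": lv, "offset_mm": off,
                               "true_dsa_mm2": round(float(a), 3)})
    pd.DataFrame(truth_rows).to_csv(out / "ground_truth_dsa.csv", index=False)

    # --- manifest ------------------------------------------------------
    manifest = build_manifest(dev_ids, test_ids, seed=seeds["manifest"])
    manifest.to_csv(out / "manifest.csv", index=False)
    counts = manifest_counts(manifest)
    (out / "manifest_counts.json").write_text(json.dumps(counts, indent=2, sort_keys=True))

    # --- assemble training data ---------------------------------------
    from .core import Label
    labeled, unlabeled = [], []
    dev_rows = manifest[manifest.split.isin(("train", "validation"))]
    for (pid, mode, level), grp in dev_rows.groupby(["patient_id", "mode", "level"], sort=False):
        stack = patients[pid].stacks[(mode, level)]
        is_labeled = bool(grp.labeled.iloc[0])
        for k in range(len(stack.offsets_mm)):
            img = stack.slices[k]
            if is_labeled:
                msk = (stack.label_slices[k] == int(Label.DURAL_SAC)).astype(np.uint8)
                labeled.append((img, msk))
            else:
                unlabeled.append(img)

    # --- train ---------------------------------------------------------
    model = DualDecoderUNet(
        DualDecoderUNetConfig(input_size=(config.input_px, config.input_px),
                              depth=config.depth, base_channels=config.base_channels),
        seed=seeds["train"],
    )
    tcfg = TrainingConfig(
        epochs=config.epochs,
        batch_size=config.batch_size,
        consistency_weight=config.consistency_weight,
        augment_enabled=config.augment,
        augmentation=AugmentParams() if config.augment else AugmentParams.identity(),
        seed=seeds["train"],
    )
    model, history = train(model, labeled, unlabeled, tcfg)
    history.to_csv(out / "training_history.csv", index=False)
    model.save(out / "model.npz")

    # --- infer + measure on the test set -------------------------------
    slice_rows = []
    test_rows = manifest[manifest.split == "test"]
    for (pid, mode, level), grp in test_rows.groupby(["patient_id", "mode", "level"], sort=False):
        stack = patients[pid].stacks[(mode, level)]
        for k, off in enumerate(stack.offsets_mm):
            pred = predict_mask(model, stack.slices[k])
            true = (stack.label_slices[k] == int(Label.DURAL_SAC)).astype(np.uint8)
            slice_rows.append({
                "patient_id": pid, "mode": mode, "level": level, "offset_mm": int(off),
                "dsa_pred": round(dsa_from_mask(pred, stack.pixel_spacing_mm), 3),
                "dsa_true": round(dsa_from_mask(true, stack.pixel_spacing_mm), 3),
                "dice": round(dice(pred, true), 4),
            })
    slice_table = pd.DataFrame(slice_rows)
    slice_table.to_csv(out / "measurements.csv", index=False)

    # --- evaluate ------------------------------------------------------
    report = evaluate_testset(slice_table)
    report.segmentation.to_csv(out / "segmentation_metrics.csv", index=False)
    report.classification.to_csv(out / "classification_metrics.csv", index=False)
    report.level_table.to_csv(out / "level_calls.csv", index=False)
    (out / "report.txt").write_text(report.render() + "\n")
    return report
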