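"""Synthetic-recovery experiments: can the model re-learn known phantoms?

The recovery experiment trains the dual-decoder U-Net on reformatted
phantom slices with exactly known dural-sac masks and scores held-out
slices by Dice.  It is the package's evidence that the training loop
optimises what it claims to; run it at full scale (160 x 160, 40
labelled + 160 unlabelled, 50 epochs) or scaled down for quick CPU
checks — the task is high-contrast, so the qualitative outcome is not
resolution-bound.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .core import LEVELS, Label
from .evaluation import dice
from .geometry import ReformatSpec, disc_centers, fit_spinal_curve, locate_centroids, reformat_level
from .nn import DualDecoderUNet, DualDecoderUNetConfig
from .phantom import _BODY_ANTERIOR_OFFSET, apply_acquisition_mode, generate_phantom, sample_config
from .training import TrainingConfig, predict_mask, train


def phantom_slice_pool(
    n_patients: int,
    input_px: int,
    pixel_mm: float,
    seed: int,
    noise_sd_hu: float = 5.0,
) -> list[tuple[np.ndarray, np.ndarray]]:
    """(image, dural-sac mask) pairs reformatted from random phantoms.

    Each patient contributes both acquisition modes, all disc levels,
    11 slices per level, windows centred on the spinal canal.
    """
    rng = np.random.default_rng(seed)
    spec = ReformatSpec(fov_mm=input_px * pixel_mm, pixel_spacing_mm=pixel_mm)
    pool: list[tuple[np.ndarray, np.ndarray]] = []
    for _ in range(n_patients):
        pcfg = sample_config(rng, noise_sd_hu=noise_sd_hu)
        vol, lab, _ = generate_phantom(pcfg)
        for mode in ("lumbar", "abdominal"):
            mvol = apply_acquisition_mode(vol, lab, mode, noise_sd_hu,
                                          seed=int(rng.integers(2**31)))
            cents = locate_centroids(mvol) - np.array([0.0, _BODY_ANTERIOR_OFFSET, 0.0])
            curve = fit_spinal_curve(cents)
            s_mid = (curve.control_arclengths[:-1] + curve.control_arclengths[1:]) / 2.0
            for j in range(len(s_mid)):
                stack = reformat_level(mvol, curve, float(s_mid[j]), level=LEVELS[j],
                                       labels=lab, spec=spec)
                for k in range(len(stack.offsets_mm)):
                    msk = (stack.label_slices[k] == int(Label.DURAL_SAC)).astype(np.uint8)
                    pool.append((stack.slices[k], msk))
    return pool


@dataclass
class RecoveryResult:
    seed: int
    consistency_weight: float
    heldout_dsc: float
    n_labeled: int
    n_unlabeled: int
    epochs: int


def dsc_recovery_experiment(
    seed: int,
    consistency_weight: float = 1.0,
    n_labeled: int = 40,
    n_unlabeled: int = 160,
    n_heldout: int = 20,
    input_px: int = 160,
    pixel_mm: float = 0.5,
    epochs: int = 50,
    batch_size: int = 8,
    n_patients: int | None = None,
) -> RecoveryResult:
    """Train from scratch on phantom slices and report held-out mean DSC."""
    need = n_labeled + n_unlabeled + n_heldout
    if n_patients is None:
        n_patients = int(np.ceil(need / 110)) + 1
    pool = phantom_slice_pool(n_patients, input_px, pixel_mm, seed=seed)
    if len(pool) < need:
        raise ValueError(f"pool of {len(pool)} slices cannot cover {need}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(pool))
    lab_idx = order[:n_labeled]
    unl_idx = order[n_labeled:n_labeled + n_unlabeled]
    hold_idx = order[n_labeled + n_unlabeled:need]
    labeled = [pool[i] for i in lab_idx]
    unlabeled = [pool[i][0] for i in unl_idx]
    heldout = [pool[i] for i in hold_idx]

    model = DualDecoderUNet(
        DualDecoderUNetConfig(input_size=(input_px, input_px)), seed=seed)
    cfg = TrainingConfig(epochs=epochs, batch_size=batch_size,
                         consistency_weight=consistency_weight, seed=seed)
    model, _ = train(model, labeled, unlabeled if consistency_weight > 0 else [], cfg)
    scores = [dice(predict_mask(model, img), msk) for img, msk in heldout]
    return RecoveryResult(seed, consistency_weight, float(np.mean(scores)),
                          n_labeled, n_unlabeled, epochs)
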