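"""Dataset manifest construction.

Mirrors the study design the pipeline emulates: every patient has both
a lumbar and an abdominal CT.  Development patients carry labels for
exactly one randomly assigned disc level (both modalities, 11 slices
each); their remaining four levels enter as unlabeled slices for
semi-supervised training.  Test patients are fully labelled at all five
levels.  With 100 development and 9 test patients this reproduces the
reference arithmetic: 2,200 labelled development images and 990 test
images (90 test levels, 45 per modality).
"""

from __future__ import annotations

from collections.abc import Sequence

import numpy as np
import pandas as pd

from .core import LEVELS, MODES

MANIFEST_COLUMNS = (
    "patient_id", "mode", "level", "offset_mm", "image_path", "label_path", "labeled", "split",
)


def _slice_rows(pid: str, mode: str, level: str, labeled: bool, split: str) -> list[dict]:
    rows = []
    for off in range(-5, 6):
        stem = f"{pid}/{mode}/{level}/off{off:+03d}"
        rows.append({
            "patient_id": pid,
            "mode": mode,
            "level": level,
            "offset_mm": off,
            "image_path": stem + "_img.npy",
            "label_path": stem + "_lab.npy" if labeled else "",
            "labeled": labeled,
            "split": split,
        })
    return rows


def build_manifest(
    dev_patients: Sequence[str],
    test_patients: Sequence[str],
    n_train: int | None = None,
    n_val: int | None = None,
    seed: int = 0,
    levels: Sequence[str] = LEVELS,
    modes: Sequence[str] = MODES,
) -> pd.DataFrame:
    """Assemble the slice-level dataset manifest.

    ``n_train``/``n_val`` split the development patients (default: the
    reference 81/19 proportion); they must sum to the development count.
    The labelled level of each development patient is drawn uniformly
    with the given seed, the same level for both modalities.
    """
    dev_patients = list(dev_patients)
    test_patients = list(test_patients)
    overlap = set(dev_patients) & set(test_patients)
    if overlap:
        raise ValueError(f"patients in both development and test sets: {sorted(overlap)}")
    n_dev = len(dev_patients)
    if n_train is None and n_val is None:
        n_train = int(round(n_dev * 0.81))
        n_val = n_dev - n_train
    if n_train + n_val != n_dev:
        raise ValueError(f"split plan {n_train}+{n_val} does not sum to {n_dev} development patients")

    rng = np.random.default_rng(seed)
    order = rng.permutation(n_dev)
    split_of = {dev_patients[i]: ("train" if rank < n_train else "validation")
                for rank, i in enumerate(order)}
    labeled_level = {pid: levels[rng.integers(len(levels))] for pid in dev_patients}

    rows: list[dict] = []
    for pid in dev_patients:
        for mode in modes:
            for level in levels:
                rows.extend(_slice_rows(pid, mode, level,
                                        labeled=(level == labeled_level[pid]),
                                        split=split_of[pid]))
    for pid in test_patients:
        for mode in modes:
            for level in levels:
                rows.extend(_slice_rows(pid, mode, level, labeled=True, split="test"))

    return pd.DataFrame(rows, columns=list(MANIFEST_COLUMNS))


def manifest_counts(manifest: pd.DataFrame) -> dict[str, int]:
    """The headline counting identities of a manifest."""
    dev = manifest[manifest.split.isin(("train", "validation"))]
    test = manifest[manifest.split == "test"]
    test_levels = test.groupby(["patient_id", "mode", "level"], sort=False).ngroups
    return {
        "dev_labeled_images": int(dev.labeled.sum()),
        "dev_unlabeled_images": int((~dev.labeled).sum()),
        "test_images": int(len(test)),
        "test_levels": test_levels,
        "test_levels_per_mode": test_levels // max(test["mode"].nunique(), 1),
        "dev_labeled_levels": dev[dev.labeled].groupby(
            ["patient_id", "mode", "level"], sort=False).ngroups,
    }
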