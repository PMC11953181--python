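"""Core in-memory containers shared by every stage of the pipeline.

Conventions
-----------
* Volumes are indexed ``[x, y, z]`` with x = left->right, y = posterior->
  anterior, z = inferior->superior.
* All physical quantities are millimetres; world coordinates are
  ``origin_mm + index * voxel_spacing_mm``.
* Label volumes are categorical grids over the fixed class set below
  (mutually exclusive by construction).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import IntEnum

import numpy as np

#: Canonical disc levels of the lumbar spine, inferior-most last.
LEVELS = ("L1-L2", "L2-L3", "L3-L4", "L4-L5", "L5-S1")

#: Acquisition modes emulated by the phantom generator.
MODES = ("lumbar", "abdominal")


class Label(IntEnum):
    """Tissue classes delineated on axial CT."""

    BACKGROUND = 0
    BONE = 1
    DURAL_SAC = 2
    DISC_POSTERIOR_MARGIN = 3
    LIGAMENTUM_FLAVUM = 4


@dataclass
class CTVolume:
    """A 3D CT intensity grid with voxel-spacing metadata.

    Intensities are Hounsfield-unit-like values (water ~ 0, cortical
    bone ~ +700).
    """

    intensities: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)
    mode: str = "lumbar"
    patient_id: str = ""

    def __post_init__(self) -> None:
        self.intensities = np.asarray(self.intensities)
        if self.intensities.ndim != 3 or self.intensities.size == 0:
            raise ValueError(
                f"expected a non-empty 3D grid, got ndim={self.intensities.ndim}"
            )
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError(f"voxel spacing must be positive, got {self.voxel_spacing_mm}")
        if self.mode not in MODES:
            raise ValueError(f"unknown acquisition mode {self.mode!r}; expected one of {MODES}")

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.intensities.shape

    def world_extent_mm(self) -> np.ndarray:
        """(min, max) world coordinates covered by the grid, per axis."""
        lo = np.asarray(self.origin_mm, float)
        hi = lo + (np.asarray(self.shape) - 1) * np.asarray(self.voxel_spacing_mm)
        return np.stack([lo, hi])


@dataclass
class LabelVolume:
    """Categorical tissue labels aligned with a :class:`CTVolume`."""

    classes: np.ndarray
    voxel_spacing_mm: tuple[float, float, float]
    origin_mm: tuple[float, float, float] = (0.0, 0.0, 0.0)

    def __post_init__(self) -> None:
        self.classes = np.asarray(self.classes)
        if self.classes.ndim != 3:
            raise ValueError("label grid must be 3D")
        valid = {int(v) for v in Label}
        present = set(np.unique(self.classes).tolist())
        if not present <= valid:
            raise ValueError(f"labels outside the known class set: {sorted(present - valid)}")

    def mask(self, label: Label) -> np.ndarray:
        return self.classes == int(label)


@dataclass
class GroundTruth:
    """Analytic ground truth carried alongside a generated phantom.

    ``dsa_profile`` maps ``(level, offset_mm)`` for integer offsets in
    -5..+5 to the true dural-sac cross-sectional area (mm^2) in the
    plane perpendicular to the spinal curve at that arc-length offset
    from the disc centre.
    """

    centroids_mm: np.ndarray
    disc_centers_mm: np.ndarray
    dsa_profile: dict[tuple[str, int], float] = field(default_factory=dict)

    def level_min_dsa(self, level: str) -> float:
        vals = [v for (lv, _), v in self.dsa_profile.items() if lv == level]
        if not vals:
            raise KeyError(f"no profile entries for level {level!r}")
        return float(min(vals))
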