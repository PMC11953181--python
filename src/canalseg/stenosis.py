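"""Dural-sac area measurement and stenosis classification.

The clinical rules: a slice (or level) is *stenotic* when the dural-sac
cross-sectional area (DSA) falls below 100 mm^2, and *severely
stenotic* below 75 mm^2.  A disc level is represented by the smallest
DSA among its 11 slices (the narrowest-slice rule), and the thresholds
are applied to that minimum.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DSA_STENOSIS_MM2 = 100.0
DSA_SEVERE_MM2 = 75.0
SLICES_PER_LEVEL = 11


@dataclass(frozen=True)
class DSAMeasurement:
    """One slice's dural-sac area."""

    patient_id: str
    mode: str
    level: str
    offset_mm: int
    dsa_mm2: float
    source: str = "algorithm"  # or "manual"

    def __post_init__(self) -> None:
        if self.dsa_mm2 < 0:
            raise ValueError("dsa_mm2 must be non-negative")
        if not -5 <= self.offset_mm <= 5:
            raise ValueError("offset_mm must lie in -5..+5")


@dataclass(frozen=True)
class StenosisCall:
    """Dichotomous and severe classifications for one unit (slice or level)."""

    granularity: str  # "slice" | "level"
    dichotomous: str  # "normal" | "stenosis"
    severe: str       # "normal" | "severe_stenosis"


def dsa_from_mask(mask: np.ndarray, pixel_spacing_mm) -> float:
    """DSA = positive-pixel count x pixel area (mm^2)."""
    mask = np.asarray(mask)
    vals = np.unique(mask)
    if not set(vals.tolist()) <= {0, 1, False, True}:
        raise ValueError(f"mask must be binary, found values {vals.tolist()}")
    if np.isscalar(pixel_spacing_mm):
        px = py = float(pixel_spacing_mm)
    else:
        px, py = map(float, pixel_spacing_mm)
    if px <= 0 or py <= 0:
        raise ValueError("pixel spacing must be positive")
    return float(mask.sum()) * px * py


def classify_dichotomous(dsa_mm2: float) -> str:
    """normal iff DSA >= 100 mm^2, else stenosis."""
    if dsa_mm2 < 0:
        raise ValueError("DSA must be non-negative")
    return "normal" if dsa_mm2 >= DSA_STENOSIS_MM2 else "stenosis"


def classify_severe(dsa_mm2: float) -> str:
    """normal iff DSA >= 75 mm^2, else severe_stenosis."""
    if dsa_mm2 < 0:
        raise ValueError("DSA must be non-negative")
    return "normal" if dsa_mm2 >= DSA_SEVERE_MM2 else "severe_stenosis"


def classify(dsa_mm2: float, granularity: str = "slice") -> StenosisCall:
    return StenosisCall(granularity, classify_dichotomous(dsa_mm2), classify_severe(dsa_mm2))


def level_summary(measurements: list[DSAMeasurement]) -> tuple[float, StenosisCall]:
    """Narrowest-slice rule: the level's DSA is the minimum over its 11
    slices; both classifications are applied to that minimum."""
    if len(measurements) != SLICES_PER_LEVEL:
        raise ValueError(
            f"need exactly {SLICES_PER_LEVEL} slice measurements per level, got {len(measurements)}"
        )
    min_dsa = min(m.dsa_mm2 for m in measurements)
    return min_dsa, classify(min_dsa, granularity="level")
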