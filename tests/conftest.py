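"""Shared fixtures: phantoms and oracle volumes built once per session."""

import numpy as np
import pytest

from canalseg import (
    CTVolume,
    Label,
    LabelVolume,
    PhantomConfig,
    generate_phantom,
)

SPAN_AREAS = {"L1-L2": 50.0, "L2-L3": 75.0, "L3-L4": 100.0, "L4-L5": 130.0, "L5-S1": 110.0}


@pytest.fixture(scope="session")
def default_phantom():
    cfg = PhantomConfig()
    vol, lab, gt = generate_phantom(cfg)
    return cfg, vol, lab, gt


@pytest.fixture(scope="session")
def span_phantom():
    """Phantom whose level DSAs span the stenosis spectrum (50-130 mm^2)."""
    cfg = PhantomConfig(level_dsa_mm2=dict(SPAN_AREAS))
    vol, lab, gt = generate_phantom(cfg)
    return cfg, vol, lab, gt


@pytest.fixture(scope="session")
def straight_phantom():
    cfg = PhantomConfig(curve_amplitude_mm=0.0)
    vol, lab, gt = generate_phantom(cfg)
    return cfg, vol, lab, gt


@pytest.fixture(scope="session")
def tilted_cylinder():
    """A cylinder of radius 6 mm tilted 30 degrees from z, with its axis
    in the x-z plane: perpendicular sections have area pi r^2, native
    axial sections pi r^2 / cos(30)."""
    r = 6.0
    sp = (0.5, 0.5, 0.5)
    shape = (160, 96, 160)
    xs = (np.arange(shape[0]) + 0.5) * sp[0]
    ys = (np.arange(shape[1]) + 0.5) * sp[1]
    zs = (np.arange(shape[2]) + 0.5) * sp[2]
    X, Y, Z = np.meshgrid(xs, ys, zs, indexing="ij")
    tan30, cos30 = np.tan(np.pi / 6), np.cos(np.pi / 6)
    cx0, cy0, zref = 15.0, 24.0, 40.0
    dx = X - (cx0 + tan30 * (Z - zref))
    dy = Y - cy0
    inside = (dx * cos30) ** 2 + dy**2 <= r * r
    origin = (0.25, 0.25, 0.25)
    vol = CTVolume(np.where(inside, 15.0, 0.0).astype(np.float32), sp, origin_mm=origin)
    lab = LabelVolume(np.where(inside, int(Label.DURAL_SAC), 0).astype(np.uint8), sp,
                      origin_mm=origin)
    axis = {"cx0": cx0, "cy0": cy0, "zref": zref, "tan": tan30, "cos": cos30, "r": r}
    return vol, lab, axis
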