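"""Synthetic spine-CT phantoms with analytically known dural-sac geometry.

The phantom emulates the anatomy that matters for central-canal-stenosis
measurement: a stack of vertebral bodies along a gently curved spinal
axis, intervertebral disc spaces, and inside the canal an elliptical
dural-sac tube whose cross-sectional area (DSA), measured perpendicular
to the spinal curve, narrows to a prescribed per-level value at each
disc centre.  Surrounding soft tissue includes a disc posterior margin
(anterior to the sac) and a ligamentum-flavum band (posterior), the two
structures whose hypertrophy produces canal stenosis.

Attenuation is a fixed pseudo-Hounsfield palette: only the *relative*
contrasts matter for segmentation learning, not scanner-accurate HU.

Two acquisition modes are emulated: non-contrast lumbar CT (1-mm
slices) and contrast-enhanced abdominal CT (2-mm slices, soft tissue
raised by a contrast offset).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .core import LEVELS, MODES, CTVolume, GroundTruth, Label, LabelVolume

# Pseudo-HU palette (relative contrasts are what matter).
HU_BACKGROUND = 0.0
HU_BONE = 700.0
HU_DISC = 60.0
HU_LIGAMENT = 80.0
HU_DURAL_SAC = 15.0
HU_CONTRAST_OFFSET = 40.0

# Fixed anatomy of the phantom cross-section (mm).
_BODY_ANTERIOR_OFFSET = 20.0   # vertebral-body centre anterior to canal centre
_BODY_SEMI_AXES = (16.0, 13.0)
_MARGIN_HALF_WIDTH = 11.0      # lateral half-width of margin / ligament bands
_BAND_GAP = 0.5                # gap between sac edge and soft-tissue bands
_BAND_THICKNESS = 4.0
_TAPER_HALF_LENGTH = 5.0       # cosine taper half-length along the curve (mm)
_MAX_SAC_SEMI_AXIS = 12.0      # sac must fit inside the bony canal


@dataclass
class PhantomConfig:
    """Parameters of one synthetic spine phantom.

    ``level_dsa_mm2`` gives, per disc level, the dural-sac area at the
    disc centre; away from the centre the sac widens back to
    ``baseline_dsa_mm2`` over a +/-5 mm cosine taper, so the disc-centre
    slice is the narrowest of each level by construction.  Defaults span
    the clinically relevant range: normal (>= 100 mm^2), stenosis
    (< 100 mm^2) and severe stenosis (< 75 mm^2).
    """

    n_vertebrae: int = 6
    vertebral_height_mm: float = 18.0
    disc_height_mm: float = 8.0
    curve_amplitude_mm: float = 8.0
    level_dsa_mm2: dict[str, float] = field(
        default_factory=lambda: {
            "L1-L2": 150.0,
            "L2-L3": 120.0,
            "L3-L4": 90.0,
            "L4-L5": 65.0,
            "L5-S1": 110.0,
        }
    )
    baseline_dsa_mm2: float = 170.0
    ellipse_aspect: float = 0.7
    voxel_spacing_mm: tuple[float, float, float] = (0.5, 0.5, 1.0)
    shape: tuple[int, int, int] = (128, 128, 160)
    mode: str = "lumbar"
    noise_sd_hu: float = 5.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_vertebrae < 2:
            raise ValueError("need at least 2 vertebrae to define a disc level")
        for name in ("vertebral_height_mm", "disc_height_mm", "baseline_dsa_mm2"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if any(s <= 0 for s in self.voxel_spacing_mm):
            raise ValueError("voxel spacing must be strictly positive")
        if not 0 < self.ellipse_aspect <= 1:
            raise ValueError("ellipse_aspect is the minor/major ratio, in (0, 1]")
        if self.mode not in MODES:
            raise ValueError(f"unknown mode {self.mode!r}")
        if len(self.level_dsa_mm2) != self.n_levels:
            raise ValueError(
                f"level_dsa_mm2 must name {self.n_levels} levels, got {len(self.level_dsa_mm2)}"
            )
        if any(a <= 0 for a in self.level_dsa_mm2.values()):
            raise ValueError("level DSAs must be positive")
        if self.baseline_dsa_mm2 < max(self.level_dsa_mm2.values()):
            raise ValueError("baseline_dsa_mm2 must be >= every level DSA (discs are narrowest)")
        a_major = np.sqrt(self.baseline_dsa_mm2 / (np.pi * self.ellipse_aspect))
        if a_major > _MAX_SAC_SEMI_AXIS:
            raise ValueError(
                f"dural-sac semi-axis {a_major:.1f} mm does not fit inside the canal "
                f"(max {_MAX_SAC_SEMI_AXIS} mm); lower baseline_dsa_mm2 or raise ellipse_aspect"
            )

    @property
    def n_levels(self) -> int:
        return self.n_vertebrae - 1

    @property
    def levels(self) -> tuple[str, ...]:
        if self.n_levels <= len(LEVELS):
            return LEVELS[: self.n_levels]
        return tuple(f"D{i + 1}" for i in range(self.n_levels))


def sample_config(rng: np.random.Generator, **overrides) -> PhantomConfig:
    """Draw a random patient phantom: per-level DSAs uniform on 45-160 mm^2.

    The range deliberately straddles both published thresholds (100 and
    75 mm^2) so cohorts contain normal, stenotic and severely stenotic
    levels.
    """
    base = PhantomConfig(**overrides)
    areas = {lv: float(rng.uniform(45.0, 160.0)) for lv in base.levels}
    amp = float(rng.uniform(0.6, 1.0) * base.curve_amplitude_mm)
    return replace(base, level_dsa_mm2=areas, curve_amplitude_mm=amp)


# ---------------------------------------------------------------------------
# geometry helpers


def _axis_xy(cfg: PhantomConfig, z: np.ndarray, extent_mm: np.ndarray):
    """Canal-axis centre (cx, cy) and its z-derivatives at heights ``z``.

    Lateral deviation is a half-period sine of the stated amplitude over
    the volume height; AP deviation a gentler full-period sine.
    """
    lz = extent_mm[2]
    cx0 = extent_mm[0] / 2.0
    cy0 = extent_mm[1] * 0.375  # canal posterior of centre; body fits anteriorly
    a = cfg.curve_amplitude_mm
    cx = cx0 + a * np.sin(np.pi * z / lz)
    cy = cy0 + 0.3 * a * np.sin(2 * np.pi * z / lz)
    dcx = a * (np.pi / lz) * np.cos(np.pi * z / lz)
    dcy = 0.3 * a * (2 * np.pi / lz) * np.cos(2 * np.pi * z / lz)
    return cx, cy, dcx, dcy


def _stack_layout(cfg: PhantomConfig, lz: float, sz: float):
    """z-extents of vertebral bodies and disc-centre heights.

    The stack is shifted by a sub-voxel amount so disc centres coincide
    with voxel-layer centres: the narrowest slice of each level is then
    actually rendered, keeping voxelized DSAs close to the analytic
    profile.
    """
    total = cfg.n_vertebrae * cfg.vertebral_height_mm + cfg.n_levels * cfg.disc_height_mm
    if total > lz:
        raise ValueError(f"vertebral stack ({total:.0f} mm) exceeds volume height ({lz:.0f} mm)")
    z0 = (lz - total) / 2.0
    first_disc = z0 + cfg.vertebral_height_mm + cfg.disc_height_mm / 2.0
    shift = (0.5 * sz - first_disc) % sz
    if z0 + shift + total > lz:
        shift -= sz
    z0 = max(z0 + shift, 0.0)
    pitch = cfg.vertebral_height_mm + cfg.disc_height_mm
    verts = [(z0 + i * pitch, z0 + i * pitch + cfg.vertebral_height_mm) for i in range(cfg.n_vertebrae)]
    discs = [v[1] + cfg.disc_height_mm / 2.0 for v in verts[:-1]]
    return verts, discs


def _taper_area(cfg: PhantomConfig, arc_dist: np.ndarray, level_area: float) -> np.ndarray:
    """Sac area as a function of |arc distance| from a disc centre.

    Squared-cosine taper from the level's (narrowest) area at the centre
    back to the baseline at +/-5 mm, constant baseline beyond.  The
    squared form is flat near the centre, so sub-voxel misalignment of
    the measurement plane barely perturbs the narrowest-slice area.
    """
    d = np.abs(arc_dist)
    a0, ac = cfg.baseline_dsa_mm2, level_area
    w = (0.5 * (1.0 - np.cos(np.pi * np.minimum(d, _TAPER_HALF_LENGTH) / _TAPER_HALF_LENGTH))) ** 2
    return ac + (a0 - ac) * w


def _sac_area_at(cfg: PhantomConfig, arc_from_disc: float, level_idx: int) -> float:
    levels = cfg.levels
    area = cfg.level_dsa_mm2[levels[level_idx]]
    return float(_taper_area(cfg, np.asarray(arc_from_disc), area))


# ---------------------------------------------------------------------------
# generation


def generate_phantom(config: PhantomConfig) -> tuple[CTVolume, LabelVolume, GroundTruth]:
    """Build one phantom: intensity volume, label volume, analytic truth.

    The dural sac is drawn slice-by-slice as an axial ellipse that is
    stretched by 1/cos(theta) along the local horizontal tilt direction
    of the spinal axis, so that its cross-section *perpendicular to the
    curve* has exactly the tapered target area.  Generation is a pure
    function of the config (the stated seed drives only acquisition
    noise, applied separately).
    """
    nx, ny, nz = config.shape
    sx, sy, sz = config.voxel_spacing_mm
    extent = np.array([nx * sx, ny * sy, nz * sz])
    verts, discs = _stack_layout(config, extent[2], sz)

    xs = (np.arange(nx) + 0.5) * sx
    ys = (np.arange(ny) + 0.5) * sy
    zs = (np.arange(nz) + 0.5) * sz
    X, Y = np.meshgrid(xs, ys, indexing="ij")

    labels = np.zeros((nx, ny, nz), dtype=np.uint8)
    intens = np.full((nx, ny, nz), HU_BACKGROUND, dtype=np.float32)

    cxs, cys, dcxs, dcys = _axis_xy(config, zs, extent)
    levels = config.levels
    aspect = config.ellipse_aspect

    for k in range(nz):
        z = zs[k]
        cx, cy, dcx, dcy = cxs[k], cys[k], dcxs[k], dcys[k]
        tilt2 = dcx * dcx + dcy * dcy
        cos_t = 1.0 / np.sqrt(1.0 + tilt2)

        # inclusive, centre-symmetric membership: the rendered layer set
        # of each vertebra is symmetric about its geometric centre, so
        # bone centroids coincide with the analytic ground truth
        in_vert = any(abs(z - (z0 + z1) / 2.0) <= (z1 - z0) / 2.0 + 1e-9 for z0, z1 in verts)
        # nearest disc centre and the arc-length distance to it
        j = int(np.argmin([abs(z - zd) for zd in discs]))
        arc = (z - discs[j]) / cos_t
        in_disc_band = not in_vert and abs(z - discs[j]) <= config.disc_height_mm / 2.0 + 1e-9

        dx, dy = X - cx, Y - cy

        # --- dural sac: perpendicular-area-exact oblique elliptic tube
        area = _sac_area_at(config, arc, j)
        a = np.sqrt(area / (np.pi * aspect))   # lateral semi-axis (perpendicular plane)
        b = aspect * a
        if tilt2 > 0:
            hx, hy = dcx / np.sqrt(tilt2), dcy / np.sqrt(tilt2)
            # compress by cos(theta) along the tilt direction: the axial
            # section is then the perpendicular ellipse stretched by
            # 1/cos(theta), whose perpendicular projection has area pi*a*b
            proj = dx * hx + dy * hy
            ddx = dx + (cos_t - 1.0) * proj * hx
            ddy = dy + (cos_t - 1.0) * proj * hy
        else:
            ddx, ddy = dx, dy
        sac = (ddx / a) ** 2 + (ddy / b) ** 2 <= 1.0

        slab_lab = np.zeros((nx, ny), dtype=np.uint8)
        slab_int = np.full((nx, ny), HU_BACKGROUND, dtype=np.float32)

        if in_vert:
            body = ((dx / _BODY_SEMI_AXES[0]) ** 2
                    + ((dy - _BODY_ANTERIOR_OFFSET) / _BODY_SEMI_AXES[1]) ** 2) <= 1.0
            slab_lab[body] = Label.BONE
            slab_int[body] = HU_BONE
        else:
            body = ((dx / _BODY_SEMI_AXES[0]) ** 2
                    + ((dy - _BODY_ANTERIOR_OFFSET) / _BODY_SEMI_AXES[1]) ** 2) <= 1.0
            slab_int[body] = HU_DISC  # bulk disc tissue (unlabelled)

        if in_disc_band:
            lateral = np.abs(dx) <= _MARGIN_HALF_WIDTH
            # posterior margin of the disc: band just anterior to the sac
            margin = lateral & (dy >= b + _BAND_GAP) & (dy <= b + _BAND_GAP + _BAND_THICKNESS)
            slab_lab[margin] = Label.DISC_POSTERIOR_MARGIN
            slab_int[margin] = HU_DISC
            # ligamentum flavum: band just posterior to the sac
            lig = lateral & (dy <= -(b + _BAND_GAP)) & (dy >= -(b + _BAND_GAP + _BAND_THICKNESS))
            slab_lab[lig] = Label.LIGAMENTUM_FLAVUM
            slab_int[lig] = HU_LIGAMENT

        slab_lab[sac] = Label.DURAL_SAC
        slab_int[sac] = HU_DURAL_SAC

        labels[:, :, k] = slab_lab
        intens[:, :, k] = slab_int

    # analytic ground truth -------------------------------------------------
    vert_centers_z = np.array([(z0 + z1) / 2.0 for z0, z1 in verts])
    vcx, vcy, _, _ = _axis_xy(config, vert_centers_z, extent)
    centroids = np.stack([vcx, vcy + _BODY_ANTERIOR_OFFSET, vert_centers_z], axis=1)

    disc_z = np.asarray(discs)
    dcx_, dcy_, _, _ = _axis_xy(config, disc_z, extent)
    disc_centers = np.stack([dcx_, dcy_ + _BODY_ANTERIOR_OFFSET, disc_z], axis=1)

    profile: dict[tuple[str, int], float] = {}
    for j, lv in enumerate(levels):
        for off in range(-5, 6):
            profile[(lv, off)] = _sac_area_at(config, float(off), j)

    # voxel centres sit at (i + 1/2) * spacing; record that as the origin
    origin = (0.5 * sx, 0.5 * sy, 0.5 * sz)
    volume = CTVolume(intens, config.voxel_spacing_mm, origin_mm=origin, mode=config.mode)
    label_vol = LabelVolume(labels, config.voxel_spacing_mm, origin_mm=origin)
    truth = GroundTruth(centroids, disc_centers, profile)
    return volume, label_vol, truth


def apply_acquisition_mode(
    volume: CTVolume,
    label: LabelVolume,
    mode: str,
    noise_sd_hu: float = 5.0,
    seed: int = 0,
) -> CTVolume:
    """Emulate the acquisition protocol on a noiseless phantom volume.

    Lumbar mode keeps native 1-mm slices with no contrast.  Abdominal
    mode raises soft-tissue attenuation (disc, ligamentum flavum) by the
    contrast offset and resamples the z axis to 2-mm slices, as in
    contrast-enhanced abdominal protocols.  Gaussian intensity noise of
    the stated sd is added in both modes.
    """
    if mode not in MODES:
        raise ValueError(f"unknown acquisition mode {mode!r}; expected one of {MODES}")
    if volume.shape != label.classes.shape:
        raise ValueError("volume and label grids are not aligned")

    out = volume.intensities.astype(np.float32).copy()
    spacing = list(volume.voxel_spacing_mm)

    if mode == "abdominal":
        soft = np.isin(label.classes, (int(Label.DISC_POSTERIOR_MARGIN), int(Label.LIGAMENTUM_FLAVUM)))
        soft |= (volume.intensities == HU_DISC)  # bulk disc tissue
        out[soft] += HU_CONTRAST_OFFSET
        # resample z to 2-mm slices, keeping the first slice position fixed
        step = 2.0 / spacing[2]
        n_old = out.shape[2]
        idx = np.arange(0.0, n_old - 1 + 1e-9, step)
        i0 = np.floor(idx).astype(int)
        i1 = np.minimum(i0 + 1, n_old - 1)
        w = (idx - i0).astype(np.float32)
        out = out[:, :, i0] * (1.0 - w) + out[:, :, i1] * w
        spacing[2] = 2.0

    if noise_sd_hu > 0:
        rng = np.random.default_rng(seed)
        out = out + rng.normal(0.0, noise_sd_hu, size=out.shape).astype(np.float32)

    return CTVolume(
        out.astype(np.float32),
        tuple(spacing),
        origin_mm=volume.origin_mm,
        mode=mode,
        patient_id=volume.patient_id,
    )


def true_dsa(
    label: LabelVolume,
    plane_origin_mm,
    plane_u,
    plane_v,
    fov_mm: float = 60.0,
    pixel_mm: float = 0.5,
    supersample: int = 4,
) -> float:
    """Ground-truth DSA: dural-sac pixel count x pixel area on a plane.

    The plane is a ``fov_mm`` x ``fov_mm`` grid of ``pixel_mm`` pixels
    centred at ``plane_origin_mm`` and spanned by the (orthonormal)
    in-plane axes ``plane_u``, ``plane_v``.  Each pixel is rasterised by
    majority coverage over ``supersample``^2 nearest-neighbour
    subsamples, which removes the moire bias plain one-sample-per-pixel
    lookup shows on oblique planes.  An empty intersection yields 0.
    """
    o = np.asarray(plane_origin_mm, float)
    u = np.asarray(plane_u, float)
    v = np.asarray(plane_v, float)
    n = int(round(fov_mm / pixel_mm))
    ss = max(int(supersample), 1)
    sub = pixel_mm / ss
    t = (np.arange(n * ss) - (n * ss - 1) / 2.0) * sub
    P = o[None, None, :] + t[:, None, None] * u[None, None, :] + t[None, :, None] * v[None, None, :]
    idx = (P - np.asarray(label.origin_mm)) / np.asarray(label.voxel_spacing_mm)
    sac = (label.classes == int(Label.DURAL_SAC)).astype(np.float32)
    vals = ndimage.map_coordinates(
        sac, idx.reshape(-1, 3).T, order=0, mode="constant", cval=0.0
    ).reshape(n, ss, n, ss)
    coverage = vals.mean(axis=(1, 3))
    # majority rule; exact half-coverage ties count one half each, so a
    # boundary running along pixel edges contributes without bias
    n_pix = (coverage > 0.5).sum() + 0.5 * (coverage == 0.5).sum()
    return float(n_pix) * pixel_mm * pixel_mm
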