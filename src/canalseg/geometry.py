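"""Spinal-curve fitting and curved planar reformation.

The measurement geometry of the pipeline: vertebral-body centroids are
located from bone attenuation, a smooth "virtual spinal curve" is
interpolated through them, and each intervertebral disc level is
resampled into a stack of 11 slices (centre +/- 5 at 1-mm intervals) on
planes perpendicular to the local curve tangent.  Areas measured on
those planes are therefore true cross-sectional areas, independent of
how obliquely the canal runs through the native axial grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from scipy.interpolate import PchipInterpolator, make_interp_spline

from .core import CTVolume, LabelVolume

BONE_THRESHOLD_HU = 300.0
MIN_COMPONENT_VOXELS_MM3 = 500.0  # reject specks below this physical volume


def locate_centroids(volume: CTVolume, threshold_hu: float = BONE_THRESHOLD_HU) -> np.ndarray:
    """Vertebral-body centroids from bone attenuation, inferior to superior.

    Thresholds at bone attenuation, takes 3D connected components and
    returns each component's centre of mass in world mm.  Intended for
    phantoms (real scanners' vertebra localisation is a separate,
    upstream problem).
    """
    bone = volume.intensities >= threshold_hu
    lab, n = ndimage.label(bone)
    if n == 0:
        raise ValueError("no bone-attenuation structures found")
    voxel_mm3 = float(np.prod(volume.voxel_spacing_mm))
    min_vox = MIN_COMPONENT_VOXELS_MM3 / voxel_mm3
    sizes = ndimage.sum_labels(np.ones_like(lab), lab, index=np.arange(1, n + 1))
    keep = np.flatnonzero(sizes >= min_vox) + 1
    if len(keep) < 2:
        raise ValueError(f"found {len(keep)} candidate vertebral bodies; need at least 2")
    coms = ndimage.center_of_mass(bone, lab, index=keep)
    pts = np.asarray(coms) * np.asarray(volume.voxel_spacing_mm) + np.asarray(volume.origin_mm)
    return pts[np.argsort(pts[:, 2])]


@dataclass
class SpinalCurve:
    """Arc-length-parameterised smooth curve through vertebral centroids.

    ``position(s)`` and ``tangent(s)`` map arc length s (mm, 0 at the
    inferior-most centroid) to world position and unit tangent.  The
    curve is a cubic spline in a chord-length parameter, re-parameterised
    numerically by arc length to ~0.01 mm accuracy.
    """

    control_points_mm: np.ndarray
    _spline: object = field(repr=False, default=None)
    _s_of_u: object = field(repr=False, default=None)
    _u_of_s: object = field(repr=False, default=None)
    length: float = 0.0
    control_arclengths: np.ndarray = None

    def position(self, s) -> np.ndarray:
        return np.asarray(self._spline(self._u_of_s(s)))

    def tangent(self, s) -> np.ndarray:
        d = np.asarray(self._spline.derivative()(self._u_of_s(s)))
        norm = np.linalg.norm(d, axis=-1, keepdims=True)
        return d / norm


def fit_spinal_curve(centroids: np.ndarray, n_samples: int = 4096) -> SpinalCurve:
    """Interpolating spline through the centroids, arc-length parameterised."""
    pts = np.asarray(centroids, float)
    if pts.ndim != 2 or pts.shape[1] != 3 or len(pts) < 2:
        raise ValueError("need >= 2 centroids as an (n, 3) array")
    dz = np.diff(pts[:, 2])
    if np.any(dz <= 0):
        raise ValueError("centroids must have strictly increasing z (no duplicates)")
    chord = np.concatenate([[0.0], np.cumsum(np.linalg.norm(np.diff(pts, axis=0), axis=1))])
    k = min(3, len(pts) - 1)
    spline = make_interp_spline(chord, pts, k=k, axis=0)

    u = np.linspace(0.0, chord[-1], n_samples)
    d = spline.derivative()(u)
    speed = np.linalg.norm(d, axis=1)
    s = np.concatenate([[0.0], np.cumsum((speed[1:] + speed[:-1]) / 2.0 * np.diff(u))])
    u_of_s = PchipInterpolator(s, u)
    s_of_u = PchipInterpolator(u, s)
    return SpinalCurve(
        control_points_mm=pts,
        _spline=spline,
        _s_of_u=s_of_u,
        _u_of_s=u_of_s,
        length=float(s[-1]),
        control_arclengths=np.asarray(s_of_u(chord)),
    )


def disc_centers(curve: SpinalCurve, centroids: np.ndarray | None = None) -> np.ndarray:
    """Disc-centre points: arc-length midpoints between adjacent centroids."""
    s_ctrl = curve.control_arclengths
    mids = (s_ctrl[:-1] + s_ctrl[1:]) / 2.0
    return np.asarray([curve.position(s) for s in mids])


@dataclass(frozen=True)
class ReformatSpec:
    """Sampling geometry of one reformatted slice.

    The clinical protocol fixes the stack at 11 slices with 1-mm
    spacing; field of view and pixel size carry no published value and
    are configurable.  ``center_offset_mm`` shifts the in-plane window (u, v) from
    the curve point — useful to centre the window on the spinal canal,
    which lies posterior to the vertebral-body centroids the curve
    interpolates.
    """

    fov_mm: float = 80.0
    pixel_spacing_mm: float = 0.5
    center_offset_mm: tuple[float, float] = (0.0, 0.0)
    n_slices: int = 11
    slice_spacing_mm: float = 1.0

    @property
    def n_pixels(self) -> int:
        return int(round(self.fov_mm / self.pixel_spacing_mm))

    @property
    def offsets_mm(self) -> np.ndarray:
        half = (self.n_slices - 1) // 2
        return np.arange(-half, half + 1) * self.slice_spacing_mm


@dataclass
class PlaneFrame:
    """Origin and orthonormal in-plane basis (u, v) with normal n = u x v."""

    origin_mm: np.ndarray
    u: np.ndarray
    v: np.ndarray
    normal: np.ndarray


@dataclass
class DiscLevelStack:
    """11 perpendicular slices through one disc level, centre +/- 5 mm."""

    level: str
    slices: np.ndarray            # (11, n, n) intensities
    label_slices: np.ndarray | None
    pixel_spacing_mm: float
    slice_thickness_mm: float
    offsets_mm: np.ndarray
    plane_frames: list[PlaneFrame]

    def __post_init__(self) -> None:
        if len(self.slices) != len(self.offsets_mm) or len(self.plane_frames) != len(self.slices):
            raise ValueError("slices, offsets and frames must agree in length")


def _initial_frame(normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First in-plane axis: projection of world x onto the plane."""
    ex = np.array([1.0, 0.0, 0.0])
    u = ex - np.dot(ex, normal) * normal
    nu = np.linalg.norm(u)
    if nu < 1e-8:  # normal parallel to x: fall back to world y
        u = np.array([0.0, 1.0, 0.0]) - normal[1] * normal
        nu = np.linalg.norm(u)
    u = u / nu
    return u, np.cross(normal, u)


def _propagate_frame(u_prev: np.ndarray, normal: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Rotation-minimising propagation: project previous u onto new plane."""
    u = u_prev - np.dot(u_prev, normal) * normal
    nu = np.linalg.norm(u)
    if nu < 1e-8:
        return _initial_frame(normal)
    u = u / nu
    return u, np.cross(normal, u)


def _sample_plane(grid: np.ndarray, spacing, origin, frame: PlaneFrame, spec: ReformatSpec, order: int):
    n = spec.n_pixels
    t = (np.arange(n) - (n - 1) / 2.0) * spec.pixel_spacing_mm
    du, dv = spec.center_offset_mm
    center = frame.origin_mm + du * frame.u + dv * frame.v
    P = (center[None, None, :]
         + (t[:, None, None] + 0.0) * frame.u[None, None, :]
         + t[None, :, None] * frame.v[None, None, :])
    idx = (P - np.asarray(origin)) / np.asarray(spacing)
    return ndimage.map_coordinates(
        grid.astype(np.float32), idx.reshape(-1, 3).T, order=order, mode="constant", cval=0.0
    ).reshape(n, n)


def reformat_level(
    volume: CTVolume,
    curve: SpinalCurve,
    disc_center_s: float,
    level: str = "",
    labels: LabelVolume | None = None,
    spec: ReformatSpec = ReformatSpec(),
) -> DiscLevelStack:
    """Resample the 11-slice perpendicular stack for one disc level.

    ``disc_center_s`` is the arc length of the disc centre on the curve.
    Intensities are sampled with trilinear interpolation; labels (when
    given) with nearest-neighbour on identical plane frames.  An offset
    whose plane centre falls outside the volume raises, naming the
    offset.
    """
    if not 0.0 <= disc_center_s <= curve.length:
        raise ValueError(f"disc centre s={disc_center_s:.1f} mm outside curve [0, {curve.length:.1f}]")
    lo, hi = volume.world_extent_mm()
    frames: list[PlaneFrame] = []
    u_prev = None
    for off in spec.offsets_mm:
        s = disc_center_s + off
        pos = np.asarray(curve.position(s), float)
        n = np.asarray(curve.tangent(s), float)
        n = n / np.linalg.norm(n)
        if np.any(pos < lo - 1e-6) or np.any(pos > hi + 1e-6):
            raise ValueError(f"slice at offset {off:+.0f} mm falls outside the volume")
        if u_prev is None:
            u, v = _initial_frame(n)
        else:
            u, v = _propagate_frame(u_prev, n)
        u_prev = u
        frames.append(PlaneFrame(pos, u, v, n))

    imgs = np.stack([
        _sample_plane(volume.intensities, volume.voxel_spacing_mm, volume.origin_mm, f, spec, order=1)
        for f in frames
    ])
    labs = None
    if labels is not None:
        labs = np.stack([
            _sample_plane(labels.classes, labels.voxel_spacing_mm, labels.origin_mm, f, spec, order=0)
            for f in frames
        ]).astype(np.uint8)
    return DiscLevelStack(
        level=level,
        slices=imgs,
        label_slices=labs,
        pixel_spacing_mm=spec.pixel_spacing_mm,
        slice_thickness_mm=spec.slice_spacing_mm,
        offsets_mm=spec.offsets_mm,
        plane_frames=frames,
    )
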