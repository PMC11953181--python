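"""Spinal curve, centroid finding and curved planar reformation."""

import numpy as np
import pytest

from canalseg import (
    CTVolume,
    Label,
    ReformatSpec,
    disc_centers,
    fit_spinal_curve,
    locate_centroids,
    reformat_level,
)


class TestLocateCentroids:
    def test_straight_phantom_collinear(self, straight_phantom):
        _, vol, _, gt = straight_phantom
        c = locate_centroids(vol)
        assert len(c) == 6
        assert np.ptp(c[:, 0]) < 1e-6
        assert np.ptp(c[:, 1]) < 1e-6

    def test_curved_phantom_within_2mm(self, default_phantom):
        _, vol, _, gt = default_phantom
        c = locate_centroids(vol)
        err = np.linalg.norm(c - gt.centroids_mm, axis=1)
        assert err.max() <= 2.0

    def test_all_background_rejected(self):
        vol = CTVolume(np.zeros((32, 32, 32), np.float32), (1.0, 1.0, 1.0))
        with pytest.raises(ValueError):
            locate_centroids(vol)


class TestFitSpinalCurve:
    def test_two_points_straight_segment(self):
        pts = np.array([[0.0, 0.0, 0.0], [0.0, 0.0, 50.0]])
        curve = fit_spinal_curve(pts)
        for s in (0.0, 17.3, 50.0):
            np.testing.assert_allclose(curve.tangent(s), [0, 0, 1], atol=1e-9)
        assert curve.length == pytest.approx(50.0, abs=1e-6)

    def test_interpolates_first_centroid(self, default_phantom):
        _, _, _, gt = default_phantom
        curve = fit_spinal_curve(gt.centroids_mm)
        np.testing.assert_allclose(curve.position(0.0), gt.centroids_mm[0], atol=1e-9)

    def test_circular_arc_midpoint(self):
        """Centroids on a circle of radius 100: the arc-length midpoint
        of the fitted spline lands within 0.5 mm of the true arc
        midpoint."""
        R = 100.0
        th = np.linspace(0, np.pi / 3, 7)
        pts = np.stack([R * (1 - np.cos(th)), np.zeros_like(th), R * np.sin(th)], axis=1)
        curve = fit_spinal_curve(pts)
        mid = curve.position(curve.control_arclengths[-1] / 2.0)
        mid_true = np.array([R * (1 - np.cos(np.pi / 6)), 0.0, R * np.sin(np.pi / 6)])
        assert np.linalg.norm(mid - mid_true) <= 0.5

    def test_unit_tangent_everywhere(self, default_phantom):
        _, _, _, gt = default_phantom
        curve = fit_spinal_curve(gt.centroids_mm)
        ss = np.linspace(0, curve.length, 33)
        norms = np.linalg.norm(np.stack([curve.tangent(s) for s in ss]), axis=1)
        np.testing.assert_allclose(norms, 1.0, atol=1e-6)

    def test_non_monotone_rejected(self):
        pts = np.array([[0, 0, 0.0], [0, 0, 10.0], [0, 0, 5.0]])
        with pytest.raises(ValueError, match="increasing z"):
            fit_spinal_curve(pts)


class TestDiscCenters:
    def test_six_centroids_give_five_centers(self, default_phantom):
        _, _, _, gt = default_phantom
        curve = fit_spinal_curve(gt.centroids_mm)
        assert len(disc_centers(curve, gt.centroids_mm)) == 5

    def test_straight_equally_spaced_midpoints(self):
        pts = np.stack([np.full(4, 3.0), np.full(4, 7.0), np.arange(4) * 20.0], axis=1)
        curve = fit_spinal_curve(pts)
        dc = disc_centers(curve, pts)
        expected = (pts[:-1] + pts[1:]) / 2.0
        np.testing.assert_allclose(dc, expected, atol=1e-6)

    def test_phantom_within_1_5mm_of_truth(self, default_phantom):
        _, vol, _, gt = default_phantom
        curve = fit_spinal_curve(locate_centroids(vol))
        dc = disc_centers(curve, None)
        err = np.linalg.norm(dc - gt.disc_centers_mm, axis=1)
        assert err.max() <= 1.5


class TestReformatLevel:
    def test_identity_on_straight_spine(self, straight_phantom):
        """Offsets on the native z-grid + straight vertical curve:
        reformatted slices equal the native axial slices."""
        _, vol, lab, gt = straight_phantom
        curve = fit_spinal_curve(locate_centroids(vol))
        s_mid = (curve.control_arclengths[0] + curve.control_arclengths[1]) / 2.0
        spec = ReformatSpec(fov_mm=48.0, pixel_spacing_mm=0.5, center_offset_mm=(0.0, 0.0))
        stack = reformat_level(vol, curve, s_mid, labels=lab, spec=spec)
        assert len(stack.slices) == 11
        span = float(vol.intensities.max() - vol.intensities.min())
        for k, off in enumerate(stack.offsets_mm):
            z = gt.disc_centers_mm[0, 2] + off
            native = vol.intensities[:, :, int(round(z - 0.5))]
            frame = stack.plane_frames[k]
            n = spec.n_pixels
            t = (np.arange(n) - (n - 1) / 2.0) * spec.pixel_spacing_mm
            ix = np.round((frame.origin_mm[0] + t - vol.origin_mm[0]) / 0.5).astype(int)
            iy = np.round((frame.origin_mm[1] + t - vol.origin_mm[1]) / 0.5).astype(int)
            okx = (ix >= 0) & (ix < native.shape[0])
            oky = (iy >= 0) & (iy < native.shape[1])
            diff = stack.slices[k][np.ix_(okx, oky)] - native[np.ix_(ix[okx], iy[oky])]
            assert np.abs(diff).max() <= 1e-4 * span

    def test_tilted_cylinder_perpendicular_vs_axial_area(self, tilted_cylinder):
        """Perpendicular reformation recovers pi r^2; the native axial
        section is larger by 1/cos(30)."""
        vol, lab, ax = tilted_cylinder
        r, cos30 = ax["r"], ax["cos"]
        zc = np.array([10.0, 30.0, 50.0, 70.0])
        pts = np.stack([ax["cx0"] + ax["tan"] * (zc - ax["zref"]),
                        np.full_like(zc, ax["cy0"]), zc], axis=1)
        curve = fit_spinal_curve(pts)
        s_mid = (curve.control_arclengths[0] + curve.control_arclengths[-1]) / 2.0
        spec = ReformatSpec(fov_mm=48.0, pixel_spacing_mm=0.5, center_offset_mm=(0.0, 0.0))
        stack = reformat_level(vol, curve, s_mid, labels=lab, spec=spec)
        area_perp = (stack.label_slices[5] == int(Label.DURAL_SAC)).sum() * 0.25
        k = int(round(ax["zref"] / 0.5 - 0.5))
        area_axial = (lab.classes[:, :, k] == int(Label.DURAL_SAC)).sum() * 0.25
        assert area_perp == pytest.approx(np.pi * r**2, rel=0.03)
        assert area_axial == pytest.approx(np.pi * r**2 / cos30, rel=0.03)

    def test_always_11_slices_and_orthonormal_frames(self, default_phantom):
        _, vol, lab, _ = default_phantom
        curve = fit_spinal_curve(locate_centroids(vol))
        s_mid = (curve.control_arclengths[2] + curve.control_arclengths[3]) / 2.0
        stack = reformat_level(vol, curve, s_mid, spec=ReformatSpec(fov_mm=32.0))
        assert len(stack.slices) == 11
        assert list(stack.offsets_mm) == list(range(-5, 6))
        for k, f in enumerate(stack.plane_frames):
            assert abs(np.dot(f.u, f.v)) < 1e-9
            np.testing.assert_allclose(np.cross(f.u, f.v), f.normal, atol=1e-9)
            s = s_mid + stack.offsets_mm[k]
            np.testing.assert_allclose(f.normal, curve.tangent(s), atol=1e-6)

    def test_resolution_consistency(self, default_phantom):
        """Halving the in-plane pixel spacing changes the measured
        dural-sac area by no more than 2%."""
        _, vol, lab, _ = default_phantom
        curve = fit_spinal_curve(locate_centroids(vol))
        s_mid = (curve.control_arclengths[1] + curve.control_arclengths[2]) / 2.0
        areas = {}
        for px in (0.5, 0.25):
            spec = ReformatSpec(fov_mm=40.0, pixel_spacing_mm=px, center_offset_mm=(0.0, -20.0))
            st = reformat_level(vol, curve, s_mid, labels=lab, spec=spec)
            areas[px] = (st.label_slices[5] == int(Label.DURAL_SAC)).sum() * px * px
        assert abs(areas[0.25] - areas[0.5]) / areas[0.5] <= 0.02

    def test_out_of_bounds_offset_reported(self, default_phantom):
        _, vol, _, _ = default_phantom
        curve = fit_spinal_curve(locate_centroids(vol))
        with pytest.raises(ValueError, match="outside"):
            reformat_level(vol, curve, curve.length + 30.0)
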