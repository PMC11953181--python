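"""Fit the virtual spinal curve and reformat a disc level.

Locates vertebral-body centroids from bone attenuation, interpolates
the spinal curve through them, and resamples the L3-L4 level into the
11-slice stack (centre +/- 5 mm at 1-mm intervals) on planes
perpendicular to the curve.  The minimum dural-sac area across the
stack should occur at the disc-centre slice (offset 0), where the
phantom narrows the canal by construction.
"""

import numpy as np

from canalseg import (
    Label,
    PhantomConfig,
    ReformatSpec,
    disc_centers,
    dsa_from_mask,
    fit_spinal_curve,
    generate_phantom,
    locate_centroids,
    reformat_level,
)

config = PhantomConfig()
volume, labels, truth = generate_phantom(config)

centroids = locate_centroids(volume)
err = np.linalg.norm(centroids - truth.centroids_mm, axis=1)
print(f"located {len(centroids)} vertebral centroids "
      f"(max error vs ground truth: {err.max():.2f} mm)")

# anchor the curve on the canal axis: in the phantom the canal runs a
# fixed 20 mm posterior to the vertebral-body centroids
canal_points = centroids - np.array([0.0, 20.0, 0.0])
curve = fit_spinal_curve(canal_points)
centers = disc_centers(curve, canal_points)
print(f"spinal curve length {curve.length:.1f} mm; {len(centers)} disc centres\n")

level_idx = 2  # L3-L4
s_mid = (curve.control_arclengths[level_idx] + curve.control_arclengths[level_idx + 1]) / 2.0
spec = ReformatSpec(fov_mm=48.0, pixel_spacing_mm=0.5)
stack = reformat_level(volume, curve, float(s_mid), level="L3-L4", labels=labels, spec=spec)

print(f"{'offset mm':>9} {'DSA mm^2':>9}")
areas = []
for k, off in enumerate(stack.offsets_mm):
    mask = (stack.label_slices[k] == int(Label.DURAL_SAC)).astype(np.uint8)
    a = dsa_from_mask(mask, stack.pixel_spacing_mm)
    areas.append(a)
    print(f"{off:+9.0f} {a:9.2f}")

k_min = int(np.argmin(areas))
print(f"\nnarrowest slice at offset {stack.offsets_mm[k_min]:+.0f} mm "
      f"(DSA {areas[k_min]:.2f} mm^2); the phantom's taper bottoms out "
      f"at the disc centre and is flat within +/-1 mm, so the measured "
      f"minimum sits at the centre up to pixelization.")
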