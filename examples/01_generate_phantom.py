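"""Generate a synthetic spine-CT phantom and verify its dural-sac areas.

Builds one phantom whose five disc levels span the stenosis spectrum,
then measures the dural-sac cross-sectional area (DSA) on the plane
perpendicular to the spinal axis at each disc centre and compares it
with the requested value.  DSA >= 100 mm^2 is normal, < 100 mm^2
stenosis, < 75 mm^2 severe stenosis.
"""

import numpy as np

from canalseg import PhantomConfig, classify_dichotomous, classify_severe, generate_phantom, true_dsa
from canalseg.phantom import _axis_xy

config = PhantomConfig(level_dsa_mm2={
    "L1-L2": 150.0, "L2-L3": 120.0, "L3-L4": 90.0, "L4-L5": 65.0, "L5-S1": 110.0,
})
volume, labels, truth = generate_phantom(config)
print(f"volume {volume.shape} at {volume.voxel_spacing_mm} mm; "
      f"{config.n_vertebrae} vertebrae, {len(config.levels)} disc levels\n")

extent = np.asarray(volume.shape) * np.asarray(volume.voxel_spacing_mm)
print(f"{'level':8} {'target':>8} {'measured':>9}  call")
for j, level in enumerate(config.levels):
    z = truth.disc_centers_mm[j, 2]
    cx, cy, dcx, dcy = _axis_xy(config, np.array([z]), extent)
    t = np.array([dcx[0], dcy[0], 1.0])
    t /= np.linalg.norm(t)
    u = np.array([1.0, 0.0, 0.0]) - t * t[0]
    u /= np.linalg.norm(u)
    origin = np.array([cx[0], cy[0], z])
    measured = true_dsa(labels, origin, u, np.cross(t, u), fov_mm=50.0, pixel_mm=0.5)
    call = classify_dichotomous(measured)
    if classify_severe(measured) == "severe_stenosis":
        call = "severe stenosis"
    print(f"{level:8} {config.level_dsa_mm2[level]:7.1f}  {measured:8.2f}  {call}")

print("\nMeasured areas come from counting labelled pixels on the "
      "perpendicular plane; agreement within a few percent of the "
      "requested areas confirms the phantom geometry.")
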