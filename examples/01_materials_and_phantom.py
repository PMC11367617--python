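"""CT-to-acoustic-property mapping on a synthetic layered head.

Builds a head phantom (scalp / porous skull shell / brain with two
target nuclei), runs the Hounsfield-unit -> porosity -> property
pipeline, and prints what the skull looks like acoustically.
"""

import numpy as np

from tfusnav import (PhantomSpec, make_phantom, porosity_from_hu,
                     properties_from_porosity)

# the mapping itself, on three representative voxels
for hu in (0.0, 500.0, 1000.0):
    phi = porosity_from_hu(np.array([hu]))[0]
    rho, c, alpha = (v[0] for v in properties_from_porosity(np.array([phi])))
    print(f"HU {hu:6.0f} -> porosity {phi:.2f} -> "
          f"rho {rho:7.1f} kg/m3, c {c:7.1f} m/s, alpha {alpha:5.2f} Np/m/MHz")

# a full phantom: default head-like ellipsoids, seeded porosity field
head = make_phantom(PhantomSpec(seed=1))
shell = (head.porosity < 1.0) & head.head_mask.astype(bool)
print(f"\nphantom volume {head.shape} at {head.voxel_size[0]:g} mm voxels")
print(f"head mask: {head.head_mask.sum()} voxels")
print(f"skull shell porosity: mean {head.porosity[shell].mean():.3f}, "
      f"range {head.porosity[shell].min():.2f}..{head.porosity[shell].max():.2f}")
for lab in head.label_ids():
    n = (head.labels == lab).sum()
    print(f"nucleus {lab} ({head.label_names[lab]}): {n} voxels "
          f"= {n * head.voxel_volume:.0f} mm3")
# Soft tissue maps to brain properties, HU=1000 to cortical bone; the
# shell sits in between according to its porosity.
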