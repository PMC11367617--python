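"""Simulated navigation session: stream jittered transducer poses (as an
optical tracking camera would deliver) and look up each pose's nearest
pre-computed beam and dose — no solving in the loop.
"""

import tempfile
from pathlib import Path

from tfusnav import (BeamLibrary, NucleusSpec, PhantomSpec, TransducerSpec,
                     make_phantom, make_pose_stream, mesh_scalp,
                     navigate_lookup, precompute_library)

spec = TransducerSpec(frequency=650e3, aperture_diameter=30.0,
                      focal_distance=40.0, standoff=5.0)
phantom = PhantomSpec(
    outer_radii=(33.0,) * 3, skull_outer_radii=(31.0,) * 3,
    skull_inner_radii=(26.0,) * 3,
    nuclei=(NucleusSpec(10, (0.0, 0.0, 0.0), (5.0, 5.0, 5.0), "target"),),
    voxel_size=1.5, seed=2)
head = make_phantom(phantom)
mesh = mesh_scalp(head.head_mask, 48, head.affine)

with tempfile.TemporaryDirectory() as tmp:
    lib_path = Path(tmp) / "beams.h5"
    precompute_library(head, mesh, spec, lib_path, config_hash="example04")

    # 2 mm / 1 degree jitter emulates optical-camera accuracy
    stream = make_pose_stream(mesh, mesh.valid_face_ids(), 10, seed=7,
                              standoff=spec.standoff,
                              position_sigma_mm=2.0, angle_sigma_deg=1.0)
    with BeamLibrary(lib_path) as lib:
        samples = navigate_lookup(stream, mesh, lib, head, label=10)

print("tracked pose -> nearest site (distance) -> target dose")
for i, s in enumerate(samples):
    if s.off_scalp:
        print(f"  sample {i:2d}: off scalp ({s.distance_mm:.1f} mm away)")
    else:
        print(f"  sample {i:2d}: face {s.face_id:3d} "
              f"({s.distance_mm:4.1f} mm) dose {s.target_dose:.4g}")
print("\nEach line is a pure lookup into the pre-computed library; this "
      "is what lets navigation refresh in real time.")
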