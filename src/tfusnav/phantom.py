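"""Synthetic head phantoms with known ground truth.

A phantom is a nest of ellipsoids — scalp surface, skull shell, brain —
voxelized on a regular grid, with ellipsoidal "nuclei" painted into the
brain as integer labels.  Skull porosity is a smooth seeded random field so
the beam solver sees the spatially varying bone structure the pipeline is
designed for.  Hounsfield units are synthesized by inverting the porosity
scaling (HU = 1000*(1 - phi)) so the phantom exercises the same material
pipeline as real CT data.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
from scipy import ndimage

from .materials import HeadModel, MaterialTable, build_head_model
from .scalp import ScalpMesh, TransducerPose

__all__ = ["PhantomSpec", "NucleusSpec", "make_phantom", "make_pose_stream"]


@dataclass(frozen=True)
class NucleusSpec:
    """One ellipsoidal target nucleus: integer label, center and semi-axes in mm."""

    label: int
    center: tuple[float, float, float]
    semi_axes: tuple[float, float, float]
    name: str = ""


@dataclass(frozen=True)
class PhantomSpec:
    """Geometry and material parameters of a layered-head phantom.

    Semi-axes are in mm, centered on the world origin.  ``skull_porosity``
    is the mean porosity of the shell; ``skull_porosity_variation`` the
    amplitude of the smooth random field added to it (both unitless, the
    field is clipped to [0, 1]).
    """

    outer_radii: tuple[float, float, float] = (75.0, 95.0, 70.0)
    skull_outer_radii: tuple[float, float, float] = (70.0, 90.0, 65.0)
    skull_inner_radii: tuple[float, float, float] = (64.0, 84.0, 59.0)
    skull_porosity: float = 0.3
    skull_porosity_variation: float = 0.15
    porosity_smoothing_mm: float = 5.0
    nuclei: tuple[NucleusSpec, ...] = (
        NucleusSpec(10, (-10.0, -15.0, 5.0), (8.0, 10.0, 8.0), "Left-Thalamus"),
        NucleusSpec(18, (24.0, 4.0, -14.0), (6.0, 7.0, 6.0), "Left-Amygdala"),
    )
    voxel_size: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be > 0")
        for inner, outer in ((self.skull_outer_radii, self.outer_radii),
                             (self.skull_inner_radii, self.skull_outer_radii)):
            if not all(i < o for i, o in zip(inner, outer)):
                raise ValueError("ellipsoid surfaces must be strictly nested")
        for nuc in self.nuclei:
            # conservative containment: nucleus bounding sphere inside the
            # inner-skull ellipsoid shrunk by that radius
            r = max(nuc.semi_axes)
            c = np.asarray(nuc.center)
            a = np.asarray(self.skull_inner_radii) - r
            if (a <= 0).any() or np.sum((c / a) ** 2) >= 1.0:
                raise ValueError(
                    f"nucleus {nuc.label} overlaps or touches the skull")


def _ellipsoid_mask(grid: tuple[np.ndarray, ...], center: Sequence[float],
                    radii: Sequence[float]) -> np.ndarray:
    q = sum(((g - c) / r) ** 2 for g, c, r in zip(grid, center, radii))
    return q <= 1.0


def _ellipsoid_frac(grid: tuple[np.ndarray, ...], center: Sequence[float],
                    radii: Sequence[float], voxel: float) -> np.ndarray:
    """Partial-volume (anti-aliased) ellipsoid indicator in [0, 1].

    Approximates the per-voxel inside fraction with a one-voxel linear
    ramp on the signed distance q-1 scaled by the local gradient of q —
    emulating the partial-volume averaging of real CT and removing the
    direction-dependent staircase noise of a binary voxelization.
    """
    q2 = sum(((g - c) / r) ** 2 for g, c, r in zip(grid, center, radii))
    q = np.sqrt(q2)
    gq = np.sqrt(sum(((g - c) / r ** 2) ** 2
                     for g, c, r in zip(grid, center, radii)))
    with np.errstate(invalid="ignore", divide="ignore"):
        dist = np.where(gq > 0, (q - 1.0) * q / gq, -1.0)
    return np.clip(0.5 - dist / voxel, 0.0, 1.0)


def make_phantom(
    spec: PhantomSpec = PhantomSpec(),
    table: MaterialTable = MaterialTable(),
    ground_truth_path: str | Path | None = None,
) -> HeadModel:
    """Voxelize a PhantomSpec into a HeadModel.

    Deterministic for a given spec (seed included).  If
    *ground_truth_path* is given, a JSON sidecar with the true nucleus
    centroids and analytic volumes is written there.
    """
    h = spec.voxel_size
    # symmetric world extent covering the scalp ellipsoid plus margin
    half = np.asarray(spec.outer_radii) + 4 * h
    n = (2 * np.ceil(half / h)).astype(int) + 1
    affine = np.diag([h, h, h, 1.0])
    affine[:3, 3] = -((n - 1) / 2.0) * h
    grid = np.meshgrid(*(affine[i, 3] + h * np.arange(n[i]) for i in range(3)),
                       indexing="ij", sparse=True)

    head = _ellipsoid_mask(grid, (0, 0, 0), spec.outer_radii)
    f_head = _ellipsoid_frac(grid, (0, 0, 0), spec.outer_radii, h)
    f_shell = (_ellipsoid_frac(grid, (0, 0, 0), spec.skull_outer_radii, h)
               - _ellipsoid_frac(grid, (0, 0, 0), spec.skull_inner_radii, h))

    shell_phi = float(spec.skull_porosity)
    if spec.skull_porosity_variation > 0:
        rng = np.random.default_rng(spec.seed)
        noise = rng.standard_normal(tuple(n))
        noise = ndimage.gaussian_filter(noise, spec.porosity_smoothing_mm / h)
        sd = noise.std()
        if sd > 0:
            noise /= sd
        phi_field = np.clip(shell_phi + spec.skull_porosity_variation * noise,
                            0.0, 1.0)
    else:
        phi_field = np.full(tuple(n), shell_phi)
    # porosity 1 in soft tissue, blended through the partial-volume shell
    phi = 1.0 - f_shell * (1.0 - phi_field)

    hu_inside = 1000.0 * (1.0 - phi)
    hu = f_head * hu_inside + (1.0 - f_head) * (-1000.0)

    labels = np.zeros(tuple(n), dtype=np.int32)
    names = {}
    truth = {}
    for nuc in spec.nuclei:
        m = _ellipsoid_mask(grid, nuc.center, nuc.semi_axes)
        labels[m] = nuc.label
        names[nuc.label] = nuc.name or f"label-{nuc.label}"
        truth[str(nuc.label)] = {
            "name": names[nuc.label],
            "center_mm": list(nuc.center),
            "semi_axes_mm": list(nuc.semi_axes),
            "volume_mm3": 4.0 / 3.0 * np.pi * float(np.prod(nuc.semi_axes)),
            "voxel_count": int(m.sum()),
        }

    if ground_truth_path is not None:
        Path(ground_truth_path).write_text(json.dumps(truth, indent=1))

    return build_head_model(hu, affine, labels, table=table,
                            label_names=names, head_mask=head)


def make_pose_stream(
    mesh: ScalpMesh,
    face_ids: Sequence[int],
    n_samples: int,
    seed: int = 0,
    *,
    standoff: float = 0.0,
    position_sigma_mm: float = 2.0,
    angle_sigma_deg: float = 1.0,
) -> list[TransducerPose]:
    """Simulate an optical-tracking pose stream around scalp-mesh sites.

    Cycles through *face_ids*, emitting each site pose perturbed by
    isotropic Gaussian positional jitter (``position_sigma_mm`` per axis)
    and a rotation of the axis by an angle ~ N(0, angle_sigma_deg) about a
    random perpendicular direction — emulating the ~2 mm / 1 degree
    accuracy of a tracking camera.  Zero sigmas give exact site poses.
    """
    if n_samples < 0:
        raise ValueError("n_samples must be >= 0")
    rng = np.random.default_rng(seed)
    out: list[TransducerPose] = []
    for k in range(n_samples):
        fid = int(face_ids[k % len(face_ids)])
        pos = mesh.face_centers[fid] + standoff * mesh.face_normals[fid]
        axis = -mesh.face_normals[fid]
        if position_sigma_mm > 0:
            pos = pos + rng.normal(0.0, position_sigma_mm, 3)
        if angle_sigma_deg > 0:
            ang = np.deg2rad(rng.normal(0.0, angle_sigma_deg))
            # random unit vector perpendicular to the axis
            v = rng.standard_normal(3)
            v -= axis * (v @ axis)
            v /= np.linalg.norm(v)
            axis = np.cos(ang) * axis + np.sin(ang) * v
            axis /= np.linalg.norm(axis)
        out.append(TransducerPose(face_id=fid, position=pos, axis=axis,
                                  standoff=standoff))
    return out
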