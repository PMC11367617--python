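"""CT-derived acoustic material model of the head.

Bone porosity is obtained by scaling CT (or pseudo-CT) Hounsfield units,
``phi = clip(1 - HU/1000, 0, 1)``, and every acoustic variable ``x``
(density, speed of sound, attenuation) is a porosity-weighted mix of its
soft-tissue (brain) and cortical-bone endpoint values,
``x = phi * x_brain + (1 - phi) * x_bone``.  Endpoint values default to the
IT'IS material database entries commonly used for transcranial ultrasound
planning.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import nibabel as nib
import numpy as np
from scipy import ndimage

__all__ = [
    "MaterialTable",
    "HeadModel",
    "WATER",
    "porosity_from_hu",
    "properties_from_porosity",
    "head_mask_from_ct",
    "build_head_model",
]

#: Acoustic properties of water / coupling gel: (density kg/m3, speed m/s,
#: attenuation Np/m).  Assigned to voxels outside the head mask because the
#: transducer couples through a gel pad or water standoff.
WATER = (1000.0, 1500.0, 0.0)


@dataclass(frozen=True)
class MaterialTable:
    """Brain / cortical-bone endpoint values for the porosity mixing rule.

    Attenuations are per-MHz values (Np/m/MHz); the solver scales them to
    the operating frequency.
    """

    rho_brain: float = 1046.0  # kg/m3
    rho_bone: float = 1908.0  # kg/m3
    c_brain: float = 1546.0  # m/s
    c_bone: float = 3514.0  # m/s
    alpha_brain: float = 6.8  # Np/m/MHz
    alpha_bone: float = 54.6  # Np/m/MHz

    def __post_init__(self) -> None:
        vals = (self.rho_brain, self.rho_bone, self.c_brain, self.c_bone,
                self.alpha_brain, self.alpha_bone)
        if any(not np.isfinite(v) or v <= 0 for v in vals):
            raise ValueError("all material endpoints must be finite and > 0")
        if self.rho_bone < self.rho_brain:
            raise ValueError("bone density must be >= brain density")
        if self.c_bone < self.c_brain:
            raise ValueError("bone sound speed must be >= brain sound speed")


#: Table used for a pipeline where the "soft tissue" endpoint is literally
#: water.  With porosity identically 1 the whole head then propagates like
#: water, which is the exact no-skull limit used in equivalence tests.
WATER_TABLE = MaterialTable(rho_brain=1000.0, rho_bone=1908.0,
                            c_brain=1500.0, c_bone=3514.0,
                            alpha_brain=1e-9, alpha_bone=54.6)


@dataclass
class HeadModel:
    """Co-registered volumes describing one subject's head.

    All volumes share ``shape`` and the voxel-index -> world-mm ``affine``.
    ``rho`` (kg/m3), ``c`` (m/s) carry SI values; ``alpha`` is stored in
    Np/m/MHz and scaled by the solver.  ``labels`` holds integer nucleus IDs
    following the Freesurfer/SAMSEG 'aseg' convention.
    """

    affine: np.ndarray
    head_mask: np.ndarray
    porosity: np.ndarray
    rho: np.ndarray
    c: np.ndarray
    alpha: np.ndarray
    labels: np.ndarray
    label_names: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.affine = np.asarray(self.affine, dtype=float)
        if self.affine.shape != (4, 4):
            raise ValueError("affine must be 4x4")
        shape = self.head_mask.shape
        for name in ("porosity", "rho", "c", "alpha", "labels"):
            vol = getattr(self, name)
            if vol.shape != shape:
                raise ValueError(f"{name} shape {vol.shape} != mask shape {shape}")
        if self.porosity.min() < -1e-9 or self.porosity.max() > 1 + 1e-9:
            raise ValueError("porosity must lie in [0, 1]")
        bad = (self.labels != 0) & ~self.head_mask.astype(bool)
        if bad.any():
            idx = tuple(int(i) for i in np.argwhere(bad)[0])
            raise ValueError(f"label voxel outside head mask at index {idx}")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.head_mask.shape

    @property
    def voxel_size(self) -> np.ndarray:
        """Voxel edge lengths in mm along each axis."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)

    @property
    def voxel_volume(self) -> float:
        """Voxel volume in mm3."""
        return float(abs(np.linalg.det(self.affine[:3, :3])))

    def label_ids(self) -> list[int]:
        ids = np.unique(self.labels)
        return [int(i) for i in ids if i != 0]

    def voxel_to_world(self, ijk: np.ndarray) -> np.ndarray:
        ijk = np.atleast_2d(ijk)
        return ijk @ self.affine[:3, :3].T + self.affine[:3, 3]

    def world_to_voxel(self, xyz: np.ndarray) -> np.ndarray:
        xyz = np.atleast_2d(xyz)
        inv = np.linalg.inv(self.affine)
        return xyz @ inv[:3, :3].T + inv[:3, 3]

    # ---- NIfTI I/O -------------------------------------------------------

    def save(self, directory: str | Path) -> None:
        """Write every volume as an uncompressed .nii file in *directory*."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for name, dtype in (("head_mask", np.uint8), ("porosity", np.float32),
                            ("rho", np.float32), ("c", np.float32),
                            ("alpha", np.float32), ("labels", np.int32)):
            vol = np.asarray(getattr(self, name), dtype=dtype)
            nib.save(nib.Nifti1Image(vol, self.affine), str(directory / f"{name}.nii"))

    @classmethod
    def load(cls, directory: str | Path,
             label_names: Mapping[int, str] | None = None) -> "HeadModel":
        directory = Path(directory)
        vols = {}
        affine = None
        for name in ("head_mask", "porosity", "rho", "c", "alpha", "labels"):
            img = nib.load(str(directory / f"{name}.nii"))
            vols[name] = np.asarray(img.dataobj)
            if affine is None:
                affine = img.affine
        return cls(affine=affine, label_names=label_names or {}, **vols)


def porosity_from_hu(hu_volume: np.ndarray) -> np.ndarray:
    """Bone porosity from Hounsfield units: ``clip(1 - HU/1000, 0, 1)``.

    HU = 0 (soft tissue / water) maps to porosity 1; HU = 1000 (dense
    cortical bone) maps to porosity 0; values outside are clipped.
    """
    hu = np.asarray(hu_volume, dtype=float)
    if not np.isfinite(hu).all():
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(hu))[0])
        raise ValueError(f"non-finite HU value at index {idx}")
    return np.clip(1.0 - hu / 1000.0, 0.0, 1.0)


def properties_from_porosity(
    porosity: np.ndarray, table: MaterialTable = MaterialTable()
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Mix brain/bone endpoints by porosity.

    Returns ``(rho, c, alpha)`` with ``x = phi*x_brain + (1-phi)*x_bone``.
    ``alpha`` is returned in Np/m/MHz (per-MHz, before frequency scaling).
    Porosity must already lie in [0, 1]; clip upstream.
    """
    phi = np.asarray(porosity, dtype=float)
    if phi.size and (phi.min() < 0 or phi.max() > 1):
        raise ValueError(
            f"porosity outside [0, 1] (range {phi.min():g}..{phi.max():g}); "
            "clip before mixing")
    rho = phi * table.rho_brain + (1.0 - phi) * table.rho_bone
    c = phi * table.c_brain + (1.0 - phi) * table.c_bone
    alpha = phi * table.alpha_brain + (1.0 - phi) * table.alpha_bone
    return rho, c, alpha


def head_mask_from_ct(ct_volume: np.ndarray, threshold: float) -> np.ndarray:
    """Binary head mask by thresholding a CT/pseudo-CT volume.

    Voxels with ``ct >= threshold`` are kept, then the largest connected
    component is selected and interior holes are filled so the mask is a
    single solid head robust to CT noise.
    """
    ct = np.asarray(ct_volume, dtype=float)
    if not np.isfinite(ct).all():
        idx = tuple(int(i) for i in np.argwhere(~np.isfinite(ct))[0])
        raise ValueError(f"non-finite CT value at index {idx}")
    raw = ct >= threshold
    if not raw.any():
        raise ValueError(
            f"empty head mask: no voxel >= {threshold} HU "
            f"(volume range {ct.min():g}..{ct.max():g} HU)")
    lab, n = ndimage.label(raw)
    if n > 1:
        counts = np.bincount(lab.ravel())
        counts[0] = 0
        raw = lab == int(np.argmax(counts))
    return ndimage.binary_fill_holes(raw)


def build_head_model(
    hu_volume: np.ndarray,
    affine: np.ndarray,
    labels: np.ndarray | None = None,
    *,
    mask_threshold: float = -200.0,
    table: MaterialTable = MaterialTable(),
    label_names: Mapping[int, str] | None = None,
    head_mask: np.ndarray | None = None,
) -> HeadModel:
    """Full material pipeline: HU volume -> HeadModel.

    Voxels outside the head mask receive water properties (gel/water
    coupling); inside, properties follow the porosity mixing rule.
    """
    hu = np.asarray(hu_volume, dtype=float)
    mask = (np.asarray(head_mask, bool) if head_mask is not None
            else head_mask_from_ct(hu, mask_threshold))
    phi = porosity_from_hu(hu)
    rho, c, alpha = properties_from_porosity(phi, table)
    rho_w, c_w, alpha_w = WATER
    rho = np.where(mask, rho, rho_w)
    c = np.where(mask, c, c_w)
    alpha = np.where(mask, alpha, alpha_w)
    if labels is None:
        labels = np.zeros(hu.shape, dtype=np.int32)
    return HeadModel(affine=np.asarray(affine, float), head_mask=mask,
                     porosity=phi, rho=rho, c=c, alpha=alpha,
                     labels=np.asarray(labels), label_names=label_names or {})
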