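"""Acoustic dose metrics and scalp maps.

The dose of a beam in a nucleus is the sum of the acoustic intensity over
the nucleus voxels (interpolated from the beam grid at each voxel center)
times the voxel volume — arbitrary units, linear in the source intensity.
A *scalp map* holds one dose value per mesh face for a given nucleus:
raw, and smoothed by iterated area-weighted neighbor averaging to
stabilize the location of its peak against mesh resolution.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Callable, Mapping

import numpy as np
import pandas as pd
from scipy import ndimage

from .materials import HeadModel
from .scalp import ScalpMesh
from .solver import BeamGrid, BeamResult

__all__ = ["ScalpMap", "nucleus_dose", "all_nuclei_doses",
           "assemble_scalp_map", "smooth_scalp_map"]


@dataclass
class ScalpMap:
    """Per-face dose for one nucleus.  Excluded faces carry NaN."""

    face_ids: np.ndarray
    raw_dose: np.ndarray
    smoothed_dose: np.ndarray
    nucleus_label: int
    transducer_spec_hash: str = ""

    def __post_init__(self) -> None:
        if not (len(self.face_ids) == len(self.raw_dose)
                == len(self.smoothed_dose)):
            raise ValueError("face_ids, raw and smoothed lengths differ")
        for d in (self.raw_dose, self.smoothed_dose):
            vals = d[np.isfinite(d)]
            if (vals < 0).any():
                raise ValueError("doses must be >= 0")

    def peak_face(self, smoothed: bool = True) -> int:
        dose = self.smoothed_dose if smoothed else self.raw_dose
        dose = np.where(np.isfinite(dose), dose, -np.inf)
        return int(self.face_ids[int(np.argmax(dose))])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"face_id": self.face_ids,
                             "raw_dose": self.raw_dose,
                             "smoothed_dose": self.smoothed_dose})

    def save_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, index=False, float_format="%.9g")

    @classmethod
    def from_frame(cls, df: pd.DataFrame, nucleus_label: int,
                   spec_hash: str = "") -> "ScalpMap":
        return cls(face_ids=df["face_id"].to_numpy(int),
                   raw_dose=df["raw_dose"].to_numpy(float),
                   smoothed_dose=df["smoothed_dose"].to_numpy(float),
                   nucleus_label=nucleus_label,
                   transducer_spec_hash=spec_hash)


def _nucleus_voxel_centers(head_model: HeadModel, label: int) -> np.ndarray:
    if label not in head_model.label_ids():
        raise KeyError(
            f"label {label} absent from label map; available: "
            f"{head_model.label_ids()}")
    ijk = np.argwhere(head_model.labels == label)
    return head_model.voxel_to_world(ijk)


def sample_intensity(intensity: np.ndarray, grid: BeamGrid,
                     points_mm: np.ndarray) -> np.ndarray:
    """Trilinear sample of a beam-grid intensity volume at world points;
    points outside the beam domain return 0."""
    loc = grid.world_to_local(points_mm)
    return ndimage.map_coordinates(
        np.asarray(intensity, np.float32), loc.T, order=1,
        mode="constant", cval=0.0).astype(np.float64)


def nucleus_dose(beam: BeamResult, head_model: HeadModel, label: int) -> float:
    """Sum of beam intensity over the nucleus voxels x voxel volume (a.u.)."""
    pts = _nucleus_voxel_centers(head_model, label)
    vals = sample_intensity(beam.intensity, beam.grid, pts)
    return float(vals.sum() * head_model.voxel_volume)


def all_nuclei_doses(beam: BeamResult, head_model: HeadModel) -> dict[int, float]:
    """Dose for every label present in the head model's label map."""
    return {lab: nucleus_dose(beam, head_model, lab)
            for lab in head_model.label_ids()}


def assemble_scalp_map(
    beam_library: Mapping[int, BeamResult] | Callable[[int], BeamResult],
    head_model: HeadModel,
    label: int,
    mesh: ScalpMesh,
    *,
    smoothing_iterations: int = 3,
    spec_hash: str = "",
) -> ScalpMap:
    """Raw + smoothed scalp map for one nucleus from a per-face beam library.

    *beam_library* maps face_id -> BeamResult (dict-like, or a callable for
    lazy loading).  Every valid mesh face must have a record; excluded
    faces are NaN in the map.
    """
    getter = (beam_library if callable(beam_library)
              else beam_library.__getitem__)
    face_ids = np.arange(mesh.n_faces)
    raw = np.full(mesh.n_faces, np.nan)
    for fid in mesh.valid_face_ids():
        try:
            beam = getter(int(fid))
        except KeyError as exc:
            raise KeyError(f"beam library has no record for face {fid}") from exc
        raw[fid] = nucleus_dose(beam, head_model, label)
    m = ScalpMap(face_ids=face_ids, raw_dose=raw, smoothed_dose=raw.copy(),
                 nucleus_label=label, transducer_spec_hash=spec_hash)
    return smooth_scalp_map(m, mesh, smoothing_iterations)


def smooth_scalp_map(scalp_map: ScalpMap, mesh: ScalpMesh,
                     iterations: int = 3) -> ScalpMap:
    """Iterated area-weighted averaging over edge-adjacent faces.

    Each iteration replaces a face's value by the area-weighted mean of
    itself and its valid edge neighbors; excluded (NaN) faces neither
    receive nor contribute.  iterations=0 returns the raw map.
    """
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    dose = scalp_map.raw_dose.copy()
    valid = np.isfinite(dose)
    areas = mesh.face_areas
    for _ in range(iterations):
        new = dose.copy()
        for fid in np.flatnonzero(valid):
            nbrs = mesh.adjacency[fid]
            nbrs = nbrs[valid[nbrs]] if len(nbrs) else nbrs
            ids = np.concatenate(([fid], nbrs)).astype(int)
            w = areas[ids]
            new[fid] = float(np.dot(w, dose[ids]) / w.sum())
        dose = new
    return replace(scalp_map, smoothed_dose=dose)
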