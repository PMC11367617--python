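"""Beam-library storage and the parallel pre-computation driver.

One HDF5 container per subject holds one group per scalp face with the
solved intensity volume and the pose/grid metadata, stamped with the
physics hash of the configuration that produced it.  Pre-computation is
resumable (existing records are skipped) and deterministic: results do
not depend on the worker count or scheduling order.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass
from pathlib import Path

import h5py
import numpy as np
from joblib import Parallel, delayed

from .config import SolverSettings
from .materials import HeadModel
from .scalp import ScalpMesh, TransducerPose, place_virtual_transducers
from .solver import BeamGrid, BeamResult, solve_beam
from .source import TransducerSpec

__all__ = ["BeamLibrary", "StaleLibraryError", "precompute_library",
           "PrecomputeStats"]

log = logging.getLogger("tfusnav.precompute")


class StaleLibraryError(RuntimeError):
    """Beam library was produced under different physics settings."""


@dataclass
class PrecomputeStats:
    n_solved: int
    n_skipped: int
    manifest_path: Path


def _face_key(fid: int) -> str:
    return f"face_{fid:06d}"


class BeamLibrary:
    """Read access to a per-subject beam library (HDF5 container)."""

    def __init__(self, path: str | Path):
        self.path = Path(path)
        self._h5 = h5py.File(self.path, "r")

    def close(self) -> None:
        self._h5.close()

    def __enter__(self) -> "BeamLibrary":
        return self

    def __exit__(self, *exc) -> None:
        self.close()

    @property
    def config_hash(self) -> str:
        return self._h5.attrs.get("config_hash", "")

    @property
    def mesh_checksum(self) -> str:
        return self._h5.attrs.get("mesh_checksum", "")

    def face_ids(self) -> list[int]:
        return sorted(int(k.split("_")[1]) for k in self._h5
                      if k.startswith("face_"))

    def __contains__(self, fid: int) -> bool:
        return _face_key(int(fid)) in self._h5

    def load(self, fid: int) -> BeamResult:
        key = _face_key(int(fid))
        if key not in self._h5:
            raise KeyError(f"beam library has no record for face {fid}")
        g = self._h5[key]
        intensity = (np.asarray(g["intensity"], np.float32)
                     * np.float32(g.attrs["scale"]))
        grid = BeamGrid(origin=np.asarray(g.attrs["origin"]),
                        u=np.asarray(g.attrs["u"]),
                        v=np.asarray(g.attrs["v"]),
                        w=np.asarray(g.attrs["w"]),
                        spacing=float(g.attrs["spacing"]),
                        shape=tuple(int(s) for s in g.attrs["shape"]))
        pose = TransducerPose(face_id=int(fid),
                              position=np.asarray(g.attrs["position"]),
                              axis=np.asarray(g.attrs["axis"]),
                              standoff=float(g.attrs["standoff"]))
        pressure = (np.asarray(g["pressure"]) if "pressure" in g else None)
        return BeamResult(intensity=intensity, grid=grid, pose=pose,
                          pressure=pressure)


def _solve_one(pose: TransducerPose, spec: TransducerSpec,
               head_model: HeadModel, settings: SolverSettings):
    t0 = time.perf_counter()
    beam = solve_beam(pose, spec, head_model,
                      c_ref=settings.c_ref,
                      impedance_steps=settings.impedance_steps,
                      taper_width=settings.taper_width,
                      alpha_exponent=settings.alpha_exponent,
                      keep_pressure=settings.keep_pressure)
    return pose, beam, time.perf_counter() - t0


def _write_record(h5: h5py.File, pose: TransducerPose, beam: BeamResult,
                  store_dtype: str) -> None:
    g = h5.create_group(_face_key(pose.face_id))
    inten = beam.intensity
    scale = float(inten.max()) or 1.0
    if store_dtype == "float16":
        data = (inten / scale).astype(np.float16)
    else:
        data = (inten / scale).astype(np.float32)
    g.create_dataset("intensity", data=data, compression="gzip",
                     compression_opts=4, track_times=False)
    g.attrs["scale"] = scale
    if beam.pressure is not None:
        g.create_dataset("pressure", data=beam.pressure.astype(np.complex64),
                         compression="gzip", compression_opts=4,
                         track_times=False)
    grid = beam.grid
    g.attrs.update({"origin": grid.origin, "u": grid.u, "v": grid.v,
                    "w": grid.w, "spacing": grid.spacing,
                    "shape": np.asarray(grid.shape),
                    "position": pose.position, "axis": pose.axis,
                    "standoff": pose.standoff})


def precompute_library(
    head_model: HeadModel,
    mesh: ScalpMesh,
    spec: TransducerSpec,
    library_path: str | Path,
    *,
    settings: SolverSettings = SolverSettings(),
    config_hash: str = "",
    workers: int = 1,
) -> PrecomputeStats:
    """Solve one beam per valid mesh face into an HDF5 library.

    Re-running with the same hash resumes: faces already present are
    skipped.  A hash mismatch raises :class:`StaleLibraryError` — e.g.
    after a standoff change the whole set must be solved anew.
    Records are written in face-id order so output is identical for any
    worker count.
    """
    library_path = Path(library_path)
    poses = place_virtual_transducers(mesh, spec.standoff)

    existing: set[int] = set()
    if library_path.exists():
        with h5py.File(library_path, "r") as h5:
            old_hash = h5.attrs.get("config_hash", "")
            if old_hash != config_hash:
                raise StaleLibraryError(
                    f"library {library_path} was built with physics hash "
                    f"{old_hash!r}, current configuration is {config_hash!r}; "
                    "delete the library and pre-compute the whole set anew")
            existing = {int(k.split("_")[1]) for k in h5 if k.startswith("face_")}

    todo = [p for p in poses if p.face_id not in existing]
    log.info("precompute: %d faces to solve, %d already present",
             len(todo), len(existing))
    if todo:
        if workers > 1:
            results = Parallel(n_jobs=workers)(
                delayed(_solve_one)(p, spec, head_model, settings) for p in todo)
        else:
            results = [_solve_one(p, spec, head_model, settings) for p in todo]
        results.sort(key=lambda r: r[0].face_id)
        with h5py.File(library_path, "a") as h5:
            h5.attrs["config_hash"] = config_hash
            h5.attrs["mesh_checksum"] = mesh.checksum()
            h5.attrs["spec"] = json.dumps({
                "frequency": spec.frequency,
                "aperture_diameter": spec.aperture_diameter,
                "focal_distance": spec.focal_distance,
                "standoff": spec.standoff,
                "source_amplitude": spec.source_amplitude})
            for pose, beam, dt in results:
                _write_record(h5, pose, beam, settings.store_dtype)
                log.info("face %d solved in %.2f s", pose.face_id, dt)

    manifest = {
        "config_hash": config_hash,
        "mesh_checksum": mesh.checksum(),
        "n_faces": len(poses),
        "face_ids": [p.face_id for p in poses],
        "standoff": spec.standoff,
    }
    manifest_path = library_path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=1, sort_keys=True))
    return PrecomputeStats(n_solved=len(todo), n_skipped=len(existing),
                           manifest_path=manifest_path)
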