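"""Scalp surface meshing and virtual transducer placement.

The head mask is iso-surfaced, lightly smoothed, and decimated to a target
face count.  Each face of the resulting scalp mesh is a candidate
("virtual") transducer site: the transducer exit plane sits at a fixed
standoff above the face center — the gel-pad thickness — and the beam axis
points inward along the face normal.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from pathlib import Path
from typing import Sequence

import numpy as np
import trimesh
from scipy import ndimage
from skimage import measure

__all__ = ["ScalpMesh", "TransducerPose", "mesh_scalp", "exclude_faces",
           "place_virtual_transducers"]


@dataclass(frozen=True)
class TransducerPose:
    """Rigid pose of a transducer: exit-plane center (mm) and inward unit axis."""

    face_id: int
    position: np.ndarray
    axis: np.ndarray
    standoff: float = 0.0

    def __post_init__(self) -> None:
        object.__setattr__(self, "position", np.asarray(self.position, float))
        ax = np.asarray(self.axis, float)
        n = np.linalg.norm(ax)
        if not n > 0:
            raise ValueError("pose axis must be nonzero")
        object.__setattr__(self, "axis", ax / n)


@dataclass
class ScalpMesh:
    """Triangulated scalp surface whose faces are virtual transducer sites.

    ``valid`` flags faces admissible for transducer placement; exclusions
    only toggle this flag, geometry and adjacency are untouched.
    """

    vertices: np.ndarray  # (nv, 3) world mm
    faces: np.ndarray  # (nf, 3) vertex indices
    face_centers: np.ndarray  # (nf, 3) mm
    face_normals: np.ndarray  # (nf, 3) outward unit
    face_areas: np.ndarray  # (nf,) mm2
    adjacency: list[np.ndarray]  # face -> edge-neighbor faces
    valid: np.ndarray = None  # (nf,) bool

    def __post_init__(self) -> None:
        if self.valid is None:
            self.valid = np.ones(len(self.faces), dtype=bool)

    @property
    def n_faces(self) -> int:
        return len(self.faces)

    @property
    def total_area(self) -> float:
        return float(self.face_areas.sum())

    def valid_face_ids(self) -> np.ndarray:
        return np.flatnonzero(self.valid)

    def checksum(self) -> str:
        import hashlib
        h = hashlib.sha256()
        h.update(np.ascontiguousarray(self.vertices, dtype=np.float64).tobytes())
        h.update(np.ascontiguousarray(self.faces, dtype=np.int64).tobytes())
        return h.hexdigest()[:16]

    @classmethod
    def from_trimesh(cls, tm: trimesh.Trimesh,
                     face_normals: np.ndarray | None = None) -> "ScalpMesh":
        adjacency = [[] for _ in range(len(tm.faces))]
        for a, b in tm.face_adjacency:
            adjacency[a].append(b)
            adjacency[b].append(a)
        return cls(
            vertices=np.asarray(tm.vertices, float),
            faces=np.asarray(tm.faces, int),
            face_centers=np.asarray(tm.triangles_center, float),
            face_normals=(np.asarray(face_normals, float)
                          if face_normals is not None
                          else np.asarray(tm.face_normals, float)),
            face_areas=np.asarray(tm.area_faces, float),
            adjacency=[np.asarray(sorted(n), int) for n in adjacency],
        )

    def to_trimesh(self) -> trimesh.Trimesh:
        return trimesh.Trimesh(self.vertices, self.faces, process=False)

    def save(self, path: str | Path) -> None:
        """Export geometry as STL or PLY (validity flags live in run metadata)."""
        self.to_trimesh().export(str(path))

    @classmethod
    def load(cls, path: str | Path) -> "ScalpMesh":
        tm = trimesh.load_mesh(str(path), process=False)
        tm.fix_normals()
        if tm.volume < 0:  # orient outward
            tm.invert()
        return cls.from_trimesh(tm)


def _cluster_decimate(tm: trimesh.Trimesh, cell: float) -> trimesh.Trimesh:
    """Vertex-clustering decimation on a uniform grid of size *cell* mm."""
    v = np.asarray(tm.vertices)
    keys = np.floor((v - v.min(axis=0)) / cell + 0.5).astype(np.int64)
    uniq, inverse = np.unique(keys, axis=0, return_inverse=True)
    new_v = np.zeros((len(uniq), 3))
    counts = np.bincount(inverse, minlength=len(uniq)).astype(float)
    for k in range(3):
        new_v[:, k] = np.bincount(inverse, weights=v[:, k],
                                  minlength=len(uniq)) / counts
    faces = inverse[np.asarray(tm.faces)]
    ok = ((faces[:, 0] != faces[:, 1]) & (faces[:, 1] != faces[:, 2])
          & (faces[:, 0] != faces[:, 2]))
    faces = faces[ok]
    # drop duplicate faces irrespective of winding, keep first occurrence
    key = np.sort(faces, axis=1)
    _, first = np.unique(key, axis=0, return_index=True)
    faces = faces[np.sort(first)]
    out = trimesh.Trimesh(new_v, faces, process=True)
    out.fix_normals()
    return out


class _ScalarSurface:
    """The scalp surface as the zero level set of a smoothed signed
    distance field (positive outside, voxel units).

    The smoothed SDF has near-unit gradient everywhere, so its gradient
    gives accurate outward normals and a damped Newton step projects
    arbitrary points onto the surface from any depth — independent of
    any particular triangulation.
    """

    def __init__(self, mask: np.ndarray, affine: np.ndarray,
                 sigma_vox: float = 1.0, pad: int = 2):
        self.affine = np.asarray(affine, float)
        self.inv = np.linalg.inv(self.affine)
        self.pad = pad
        m = np.pad(mask.astype(bool), pad)
        sdf = (ndimage.distance_transform_edt(~m)
               - ndimage.distance_transform_edt(m)).astype(np.float32)
        self.field = ndimage.gaussian_filter(sdf, sigma=sigma_vox)
        self.grad = np.gradient(self.field)
        # separate, more heavily smoothed gradient for normal estimates:
        # the EDT is faceted at the voxel scale, which projection
        # tolerates but normal directions do not
        self.grad_n = np.gradient(ndimage.gaussian_filter(sdf, sigma=3.0))

    def _to_vox(self, world: np.ndarray) -> np.ndarray:
        return (world @ self.inv[:3, :3].T + self.inv[:3, 3]) + self.pad

    def _sample(self, vol: np.ndarray, vox: np.ndarray) -> np.ndarray:
        return ndimage.map_coordinates(vol, vox.T, order=1, mode="nearest")

    def value(self, world: np.ndarray) -> np.ndarray:
        return self._sample(self.field, self._to_vox(np.atleast_2d(world)))

    def normals(self, world: np.ndarray) -> np.ndarray:
        """Outward unit normals (the SDF increases outward)."""
        vox = self._to_vox(np.atleast_2d(world))
        g = np.stack([self._sample(gi, vox) for gi in self.grad_n], axis=1)
        # gradients transform with the inverse-transpose of voxel->world
        n = g @ self.inv[:3, :3]
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def project(self, world: np.ndarray, iterations: int = 8) -> np.ndarray:
        """Damped Newton projection onto the 0.5 iso-surface (world mm).

        Steps are clamped to one voxel so points in flat regions of the
        field walk toward the surface instead of overshooting.
        """
        vox = self._to_vox(np.atleast_2d(world)).copy()
        for _ in range(iterations):
            f = self._sample(self.field, vox)
            g = np.stack([self._sample(gi, vox) for gi in self.grad], axis=1)
            g2 = np.einsum("ij,ij->i", g, g)
            g2[g2 < 1e-12] = np.inf
            step = (f / g2)[:, None] * g
            norm = np.linalg.norm(step, axis=1, keepdims=True)
            step *= np.minimum(1.0, 2.0 / np.maximum(norm, 1e-30))
            vox -= step
        return (vox - self.pad) @ self.affine[:3, :3].T + self.affine[:3, 3]


def _relax_on_surface(coarse: trimesh.Trimesh, surface: _ScalarSurface,
                      iterations: int = 5) -> trimesh.Trimesh:
    """Tangential vertex relaxation constrained to the level-set surface.

    Moves every vertex to the centroid of its graph neighbors, then
    projects back onto the surface; equalizes triangle shapes so face
    normals track the underlying scalp instead of the accidents of
    clustering.  Topology is unchanged.
    """
    from scipy.sparse import coo_matrix
    n = len(coarse.vertices)
    e = coarse.edges_unique
    rows = np.concatenate([e[:, 0], e[:, 1]])
    cols = np.concatenate([e[:, 1], e[:, 0]])
    A = coo_matrix((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    deg = np.asarray(A.sum(axis=1)).ravel()
    deg[deg == 0] = 1.0
    v = np.asarray(coarse.vertices)
    for _ in range(iterations):
        v = surface.project((A @ v) / deg[:, None])
    out = trimesh.Trimesh(v, coarse.faces, process=False)
    out.fix_normals()
    return out


def mesh_scalp(
    head_mask: np.ndarray,
    target_face_count: int,
    affine: np.ndarray | None = None,
    *,
    tolerance: float = 0.10,
    smoothing_iterations: int = 2,
) -> ScalpMesh:
    """Extract and decimate the scalp surface of a solid head mask.

    Marching cubes at the 0.5 iso-level, a couple of Taubin smoothing
    passes to suppress voxel staircase artifacts, then vertex-clustering
    decimation tuned (by bisection on the cluster size) until the face
    count lies within ``tolerance`` of *target_face_count*.
    """
    mask = np.asarray(head_mask)
    if not mask.any():
        raise ValueError("head mask is empty")
    if affine is None:
        affine = np.eye(4)
    # iso-surface the mask as a smoothed scalar field: sub-voxel accurate
    # and free of the 45-degree staircase facets of a binary surface
    surface = _ScalarSurface(mask, affine)
    verts, faces, _, _ = measure.marching_cubes(surface.field, level=0.0)
    verts -= surface.pad
    verts = verts @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    tm = trimesh.Trimesh(verts, faces, process=True)
    if not tm.is_watertight:
        raise ValueError("extracted scalp surface is not closed")
    if smoothing_iterations > 0:
        trimesh.smoothing.filter_taubin(tm, iterations=smoothing_iterations)

    if target_face_count >= len(tm.faces):
        tm.fix_normals()
        if tm.volume < 0:
            tm.invert()
        return ScalpMesh.from_trimesh(tm)

    # face count decreases monotonically (up to noise) with cluster size;
    # bisect, keeping the best watertight candidate seen
    cell0 = float(np.sqrt(2.0 * tm.area / target_face_count))
    lo, hi = cell0 / 4.0, cell0 * 4.0
    result, best_err = None, np.inf
    for _ in range(30):
        cell = 0.5 * (lo + hi)
        cand = _cluster_decimate(tm, cell)
        nf = len(cand.faces)
        err = abs(nf - target_face_count)
        if cand.is_watertight and err < best_err:
            result, best_err = cand, err
        if best_err <= 0.5 * tolerance * target_face_count:
            break
        if nf > target_face_count:
            lo = cell
        else:
            hi = cell
    if result is None or best_err > tolerance * target_face_count:
        raise ValueError(
            f"could not decimate to {target_face_count}±{tolerance:.0%} faces")
    result = _relax_on_surface(result, surface)
    if result.volume < 0:
        result.invert()
    normals = surface.normals(result.triangles_center)
    flip = np.einsum("ij,ij->i", normals, result.face_normals) < 0
    normals[flip] *= -1.0
    return ScalpMesh.from_trimesh(result, normals)


def exclude_faces(
    mesh: ScalpMesh,
    exclusion: dict | Sequence[int],
) -> ScalpMesh:
    """Flag faces inadmissible for transducer placement.

    *exclusion* is either an explicit sequence of face ids, or a dict:
    ``{"type": "plane", "point": [x,y,z], "normal": [nx,ny,nz]}`` excludes
    faces whose center lies on the negative side of the plane (dot product
    with the normal < 0); ``{"type": "box", "min": ..., "max": ...}``
    excludes faces whose center falls inside the box.  Returns a new mesh
    sharing geometry, with updated validity flags.
    """
    valid = mesh.valid.copy()
    if isinstance(exclusion, dict):
        kind = exclusion.get("type")
        c = mesh.face_centers
        if kind == "plane":
            point = np.asarray(exclusion["point"], float)
            normal = np.asarray(exclusion["normal"], float)
            valid &= (c - point) @ normal >= 0
        elif kind == "box":
            lo = np.asarray(exclusion["min"], float)
            hi = np.asarray(exclusion["max"], float)
            inside = np.all((c >= lo) & (c <= hi), axis=1)
            valid &= ~inside
        else:
            raise ValueError(f"unknown exclusion type {kind!r}")
    else:
        idx = np.asarray(list(exclusion), int)
        valid[idx] = False
    if not valid.any():
        raise ValueError("exclusion removed every face")
    return replace(mesh, valid=valid)


def place_virtual_transducers(mesh: ScalpMesh, standoff_mm: float) -> list[TransducerPose]:
    """One TransducerPose per valid face, at fixed standoff above the scalp.

    Exit-plane center = face center + standoff * outward normal; beam axis
    = inward normal.
    """
    if standoff_mm < 0:
        raise ValueError("standoff must be >= 0")
    poses = []
    for fid in mesh.valid_face_ids():
        n = mesh.face_normals[fid]
        poses.append(TransducerPose(
            face_id=int(fid),
            position=mesh.face_centers[fid] + standoff_mm * n,
            axis=-n,
            standoff=standoff_mm,
        ))
    return poses
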