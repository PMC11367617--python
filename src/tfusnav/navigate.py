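"""Navigation lookup: map tracked transducer poses to precomputed beams.

During a session the tracked pose is matched to the nearest virtual
transducer site and that site's precomputed doses are displayed — a pure
lookup, no solving.  The pose-to-site metric combines Euclidean position
distance with an axis-angle term, ``|dp| + w * (1 - cos theta)`` (mm,
with *w* in mm per radian), and a positional gate flags poses that are
off the scalp entirely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.spatial import cKDTree

from .dose import all_nuclei_doses
from .materials import HeadModel
from .pipeline import BeamLibrary
from .scalp import ScalpMesh, TransducerPose, place_virtual_transducers

__all__ = ["NavigationSample", "PoseIndex", "navigate_lookup"]


@dataclass
class NavigationSample:
    face_id: Optional[int]  # None when off-scalp
    off_scalp: bool
    distance_mm: float
    target_dose: Optional[float] = None
    all_doses: dict = field(default_factory=dict)


class PoseIndex:
    """Spatial index over virtual transducer sites for O(log n) lookups."""

    def __init__(self, mesh: ScalpMesh, standoff: float,
                 angle_weight_mm: float = 10.0):
        self.sites = place_virtual_transducers(mesh, standoff)
        self.positions = np.array([s.position for s in self.sites])
        self.axes = np.array([s.axis for s in self.sites])
        self.face_ids = np.array([s.face_id for s in self.sites])
        self.w = float(angle_weight_mm)
        self._tree = cKDTree(self.positions)

    def _combined(self, pose: TransducerPose, idx: np.ndarray) -> np.ndarray:
        dp = np.linalg.norm(self.positions[idx] - pose.position, axis=1)
        cos = np.clip(self.axes[idx] @ pose.axis, -1.0, 1.0)
        return dp + self.w * (1.0 - cos)

    def query(self, pose: TransducerPose) -> tuple[int, float, float]:
        """Best site by the combined metric (exact).

        Returns (face_id, positional distance mm, combined metric).  The
        angle term is bounded by 2w, so every site within
        ``best_upper_bound`` of the pose position is examined.
        """
        k = min(len(self.sites), 8)
        d0, i0 = self._tree.query(pose.position, k=k)
        i0 = np.atleast_1d(i0)
        upper = float(np.min(self._combined(pose, i0)))
        cand = self._tree.query_ball_point(pose.position, upper + 1e-9)
        cand = np.asarray(sorted(set(cand) | set(int(i) for i in i0)))
        metric = self._combined(pose, cand)
        order = np.lexsort((self.face_ids[cand], metric))
        best = cand[order[0]]
        dp = float(np.linalg.norm(self.positions[best] - pose.position))
        return int(self.face_ids[best]), dp, float(metric[order[0]])


def navigate_lookup(
    pose_stream: Sequence[TransducerPose],
    mesh: ScalpMesh,
    beam_library: BeamLibrary,
    head_model: HeadModel,
    label: int,
    *,
    gate_mm: float = 10.0,
    angle_weight_mm: float = 10.0,
) -> list[NavigationSample]:
    """Resolve each tracked pose to its nearest site and report doses.

    Doses are computed once per face on first visit and cached, so the
    loop itself never solves a beam.  Poses whose nearest site is farther
    than *gate_mm* (position) are flagged off-scalp.
    """
    if label not in head_model.label_ids():
        raise KeyError(f"label {label} absent; available {head_model.label_ids()}")
    # site standoff comes from the poses stored in the library
    standoff = 0.0
    fids = beam_library.face_ids()
    if fids:
        standoff = beam_library.load(fids[0]).pose.standoff
    index = PoseIndex(mesh, standoff, angle_weight_mm)
    cache: dict[int, dict[int, float]] = {}
    out: list[NavigationSample] = []
    for pose in pose_stream:
        fid, dp, _ = index.query(pose)
        if dp > gate_mm:
            out.append(NavigationSample(face_id=None, off_scalp=True,
                                        distance_mm=dp))
            continue
        if fid not in cache:
            cache[fid] = all_nuclei_doses(beam_library.load(fid), head_model)
        doses = cache[fid]
        out.append(NavigationSample(face_id=fid, off_scalp=False,
                                    distance_mm=dp,
                                    target_dose=doses[label],
                                    all_doses=dict(doses)))
    return out
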