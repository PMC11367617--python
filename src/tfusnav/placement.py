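"""Transducer placement strategies and dose comparison statistics.

Three placements are compared:

* LOST (line-of-sight targeting): the target centroid lies on the device
  centerline at a tissue depth equal to the focal distance in water; skull
  effects are ignored when choosing the pose, but the reported dose is
  evaluated with the full skull-aware solve at that pose.
* Water: scalp maps computed from a single water-only beam rigidly moved
  to every candidate face — skull ignored entirely.
* MBN (model-based navigation): the face maximizing the smoothed
  skull-aware scalp map.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .dose import ScalpMap, nucleus_dose, sample_intensity, smooth_scalp_map
from .materials import HeadModel
from .scalp import ScalpMesh, TransducerPose, place_virtual_transducers
from .solver import BeamResult, build_beam_grid, solve_beam
from .source import TransducerSpec

__all__ = ["PlacementResult", "DoseReport", "lost_placement",
           "water_scalp_map", "mbn_optimum", "compare_methods"]


@dataclass
class PlacementResult:
    method: str  # "LOST" | "Water" | "MBN"
    pose: Optional[TransducerPose]
    dose: float
    label: int
    spec: Optional[TransducerSpec] = None

    def __post_init__(self) -> None:
        if self.dose < 0:
            raise ValueError("dose must be >= 0")


def _label_centroid(head_model: HeadModel, label: int) -> np.ndarray:
    if label not in head_model.label_ids():
        raise KeyError(f"label {label} absent; available {head_model.label_ids()}")
    ijk = np.argwhere(head_model.labels == label)
    return head_model.voxel_to_world(ijk).mean(axis=0)


def lost_placement(
    head_model: HeadModel,
    mesh: ScalpMesh,
    spec: TransducerSpec,
    label: int,
    *,
    t_max: float = 30.0,
    evaluate_dose: bool = True,
    **solve_kwargs,
) -> PlacementResult:
    """Line-of-sight placement aiming the centerline at the target centroid.

    For each valid scalp face the transducer axis points from the face
    center to the centroid; the gel-pad thickness t = f - depth must lie
    in [0, t_max] for the water focus to land on the centroid.  Among
    feasible entries the one with the most perpendicular incidence
    (largest cosine between the inward axis and the inward surface
    normal) wins; ties prefer the thinner pad, then the lower face id.
    The reported dose is a full skull-aware solve at the selected pose.
    """
    centroid = _label_centroid(head_model, label)
    f = spec.focal_distance
    best = None  # (-score, t, fid, pose)
    for fid in mesh.valid_face_ids():
        entry = mesh.face_centers[fid]
        dvec = centroid - entry
        depth = float(np.linalg.norm(dvec))
        t = f - depth
        if not (0.0 <= t <= t_max):
            continue
        axis = dvec / depth
        score = float(axis @ -mesh.face_normals[fid])
        key = (-score, t, int(fid))
        if best is None or key < best[0]:
            pose = TransducerPose(face_id=int(fid), position=entry - t * axis,
                                  axis=axis, standoff=t)
            best = (key, pose)
    if best is None:
        raise ValueError(
            f"no feasible line-of-sight entry: target deeper than f = {f} mm "
            f"(+ pad up to {t_max} mm) from every valid face; "
            "consider a longer focal distance")
    pose = best[1]
    dose = 0.0
    if evaluate_dose:
        beam = solve_beam(pose, spec, head_model, **solve_kwargs)
        dose = nucleus_dose(beam, head_model, label)
    return PlacementResult(method="LOST", pose=pose, dose=dose, label=label,
                           spec=spec)


def water_scalp_map(
    water_beam: BeamResult,
    mesh: ScalpMesh,
    head_model: HeadModel,
    label: int,
    spec: TransducerSpec,
    *,
    standoff: float | None = None,
    smoothing_iterations: int = 3,
) -> ScalpMap:
    """Scalp map from one water-only solve rigidly moved to every face.

    The ideal water beam (radially symmetric about its axis) is
    transformed to each face's pose and the nucleus dose is summed — no
    per-face propagation.  This is the 'Water' generalization of LOST.
    """
    standoff = spec.standoff if standoff is None else standoff
    ijk = np.argwhere(head_model.labels == label)
    if len(ijk) == 0:
        raise KeyError(f"label {label} absent; available {head_model.label_ids()}")
    pts = head_model.voxel_to_world(ijk)
    vol = head_model.voxel_volume
    raw = np.full(mesh.n_faces, np.nan)
    for pose in place_virtual_transducers(mesh, standoff):
        grid = build_beam_grid(pose, spec)
        vals = sample_intensity(water_beam.intensity, grid, pts)
        raw[pose.face_id] = float(vals.sum() * vol)
    m = ScalpMap(face_ids=np.arange(mesh.n_faces), raw_dose=raw,
                 smoothed_dose=raw.copy(), nucleus_label=label)
    return smooth_scalp_map(m, mesh, smoothing_iterations)


def mbn_optimum(
    scalp_map: ScalpMap,
    mesh: ScalpMesh | None = None,
    *,
    standoff: float = 0.0,
    spec: TransducerSpec | None = None,
) -> PlacementResult:
    """Model-based optimum: the face with maximal smoothed dose.

    Ties break to the lowest face id.  The reported dose is the *raw*
    dose at that face.  If *mesh* is given the corresponding pose is
    attached.
    """
    sm = np.where(np.isfinite(scalp_map.smoothed_dose),
                  scalp_map.smoothed_dose, -np.inf)
    if not np.isfinite(sm).any():
        raise ValueError("scalp map has no valid face")
    fid = int(scalp_map.face_ids[int(np.argmax(sm))])  # argmax -> lowest id
    pose = None
    if mesh is not None:
        n = mesh.face_normals[fid]
        std = spec.standoff if spec is not None else standoff
        pose = TransducerPose(face_id=fid,
                              position=mesh.face_centers[fid] + std * n,
                              axis=-n, standoff=std)
    raw = float(scalp_map.raw_dose[np.asarray(scalp_map.face_ids) == fid][0])
    return PlacementResult(method="MBN", pose=pose, dose=raw,
                           label=scalp_map.nucleus_label, spec=spec)


@dataclass
class DoseReport:
    """Group statistics of doses per placement method.

    ``stats`` has one row per method (n, mean, sd, min, max,
    min_max_ratio); ``percent_change`` is 100*(mean_MBN - mean_LOST)
    / mean_LOST; the p-value is a two-sided two-sample t-test between the
    MBN and LOST groups (Welch by default).
    """

    stats: pd.DataFrame
    percent_change: float
    t_statistic: float
    t_pvalue: float
    equal_var: bool = False
    infinite_ratio_methods: tuple[str, ...] = ()

    def save(self, path_prefix: str | Path) -> None:
        prefix = Path(path_prefix)
        self.stats.to_csv(prefix.with_suffix(".csv"))
        meta = {"percent_change": self.percent_change,
                "t_statistic": self.t_statistic,
                "t_pvalue": self.t_pvalue,
                "equal_var": self.equal_var,
                "infinite_ratio_methods": list(self.infinite_ratio_methods)}
        prefix.with_suffix(".json").write_text(json.dumps(meta, indent=1))


def compare_methods(
    dose_table: Mapping[str, Sequence[float]] | pd.DataFrame,
    *,
    equal_var: bool = False,
) -> DoseReport:
    """Compare per-subject doses across placement methods.

    *dose_table* maps method name -> dose values (one per subject), or is
    a DataFrame with ``method`` and ``dose`` columns.  Requires MBN and
    LOST groups with >= 2 subjects each for the t-test.  A group whose
    minimum dose is zero gets an infinite min:max ratio and is flagged.
    """
    if isinstance(dose_table, pd.DataFrame):
        groups = {m: g["dose"].to_numpy(float)
                  for m, g in dose_table.groupby("method")}
    else:
        groups = {m: np.asarray(v, float) for m, v in dose_table.items()}
    for m in ("MBN", "LOST"):
        if m not in groups:
            raise KeyError(f"dose table lacks a {m!r} group")
        if len(groups[m]) < 2:
            raise ValueError(f"need >= 2 subjects in group {m!r} for the t-test")

    rows, flagged = [], []
    for m, v in groups.items():
        vmin, vmax = float(v.min()), float(v.max())
        if vmin <= 0:
            ratio = float("inf")
            flagged.append(m)
        else:
            ratio = vmax / vmin
        rows.append({"method": m, "n": len(v), "mean": float(v.mean()),
                     "sd": float(v.std(ddof=1)) if len(v) > 1 else 0.0,
                     "min": vmin, "max": vmax, "min_max_ratio": ratio})
    stats_df = pd.DataFrame(rows).set_index("method")

    mean_lost = stats_df.loc["LOST", "mean"]
    mean_mbn = stats_df.loc["MBN", "mean"]
    pct = 100.0 * (mean_mbn - mean_lost) / mean_lost
    t, p = stats.ttest_ind(groups["MBN"], groups["LOST"], equal_var=equal_var)
    return DoseReport(stats=stats_df, percent_change=float(pct),
                      t_statistic=float(t), t_pvalue=float(p),
                      equal_var=equal_var,
                      infinite_ratio_methods=tuple(flagged))
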