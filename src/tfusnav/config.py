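"""Run configuration: JSON (de)serialization and the physics hash.

A beam library is only valid for the exact physics that produced it —
transducer geometry, standoff, material endpoints, solver settings —
because e.g. changing the gel-pad thickness moves every virtual
transducer and requires re-solving the whole set.  The physics hash
stamps each library so stale ones are rejected instead of silently
reused.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from .materials import MaterialTable
from .source import TransducerSpec

__all__ = ["SolverSettings", "RunConfig"]


@dataclass(frozen=True)
class SolverSettings:
    c_ref: float = 1500.0  # m/s background for the angular-spectrum step
    impedance_steps: bool = True
    taper_width: int = 8  # absorbing-strip width, voxels
    alpha_exponent: float = 1.0  # attenuation frequency power law
    store_dtype: str = "float16"  # library intensity precision
    keep_pressure: bool = False


@dataclass
class RunConfig:
    """Everything needed to run the pipeline end to end."""

    head_dir: str = ""  # directory of HeadModel NIfTI volumes
    output_dir: str = "out"
    transducer: TransducerSpec = field(default_factory=TransducerSpec)
    material_table: MaterialTable = field(default_factory=MaterialTable)
    solver: SolverSettings = field(default_factory=SolverSettings)
    target_face_count: int = 1000
    mesh_tolerance: float = 0.10
    mesh_smoothing_iterations: int = 2
    exclusions: list = field(default_factory=list)
    map_smoothing_iterations: int = 3
    mask_threshold: float = -200.0
    target_label: int = 10
    t_max: float = 30.0  # LOST maximum pad thickness, mm
    gate_mm: float = 10.0  # navigation off-scalp gate
    angle_weight_mm: float = 10.0  # mm per radian in the pose metric
    workers: int = 1
    seed: int = 0

    # ---- JSON ------------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "transducer" in d:
            d["transducer"] = TransducerSpec(**d["transducer"])
        if "material_table" in d:
            d["material_table"] = MaterialTable(**d["material_table"])
        if "solver" in d:
            d["solver"] = SolverSettings(**d["solver"])
        return cls(**d)

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        return cls.from_dict(json.loads(Path(path).read_text()))

    # ---- physics hash ----------------------------------------------------

    def physics_hash(self) -> str:
        """Hash of every field that changes the beam solutions."""
        physics = {
            "transducer": asdict(self.transducer),
            "material_table": asdict(self.material_table),
            "solver": {k: v for k, v in asdict(self.solver).items()
                       if k != "keep_pressure"},
            "mask_threshold": self.mask_threshold,
        }
        blob = json.dumps(physics, sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]
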