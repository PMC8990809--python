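"""Run configuration: YAML loading, validation and defaults.

Defaults follow the published analysis parameters where they exist
(15 A cluster cutoff, 4 A contact cutoff, 0.5/0.8 nm dual cutoff,
four-fold symmetry); everything else is a documented package choice.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .poses import SPECIES

__all__ = ["RunConfig", "load_config", "config_hash"]


_SCHEMA: dict[str, tuple[type, ...]] = {
    # field -> accepted types (None allowed where a default of None is set)
    "structure": (str, type(None)),
    "poses": (str, type(None)),
    "trajectory": (str, type(None)),
    "trajectory_topology": (str, type(None)),
    "species": (str,),
    "state_label": (str,),
    "symmetry_order": (int,),
    "midplane_z": (int, float),
    "intracellular_boundary_z": (int, float),
    "cluster_cutoff": (int, float),
    "contact_cutoff": (int, float),
    "r_on_nm": (int, float),
    "r_off_nm": (int, float),
    "tolerance_deg": (int, float),
    "cluster_mode": (str,),
    "min_edge_pct": (int, float),
    "grid_spacing": (int, float),
    "leaflet": (str,),
    "lipid_resnames": (list,),
    "frame_stride_ps": (int, float),
    "sasa_rel_threshold": (int, float),
    "out_dir": (str, type(None)),
    "seed": (int,),
    "write_representatives": (bool,),
}


@dataclass
class RunConfig:
    """All knobs of the two workflows, with the published parameters as
    defaults where the source analysis states them."""

    structure: str | None = None
    poses: str | None = None
    trajectory: str | None = None
    trajectory_topology: str | None = None
    species: str = "PI45P2"
    state_label: str = ""
    symmetry_order: int = 4
    midplane_z: float = 0.0
    intracellular_boundary_z: float = -20.0
    cluster_cutoff: float = 15.0       # angstrom
    contact_cutoff: float = 4.0        # angstrom
    r_on_nm: float = 0.5
    r_off_nm: float = 0.8
    tolerance_deg: float = 15.0
    cluster_mode: str = "all_centroids"
    min_edge_pct: float = 5.0
    grid_spacing: float = 2.0          # angstrom
    leaflet: str = "both"
    lipid_resnames: list[str] = field(default_factory=lambda: ["POP3", "POPI", "PIP3"])
    frame_stride_ps: float = 1000.0
    sasa_rel_threshold: float = 0.20
    out_dir: str | None = None
    seed: int = 0
    write_representatives: bool = False

    def validate(self) -> "RunConfig":
        if self.species not in SPECIES:
            raise ValueError(f"unknown species {self.species!r}; expected one of {SPECIES}")
        for name in ("cluster_cutoff", "contact_cutoff", "r_on_nm", "r_off_nm",
                     "grid_spacing", "frame_stride_ps"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.r_on_nm > self.r_off_nm:
            raise ValueError("r_on_nm must be <= r_off_nm")
        if self.symmetry_order < 1:
            raise ValueError("symmetry_order must be >= 1")
        if not self.intracellular_boundary_z < self.midplane_z:
            raise ValueError("intracellular_boundary_z must be < midplane_z")
        if self.cluster_mode not in ("all_centroids", "inositol_only"):
            raise ValueError(f"unknown cluster_mode {self.cluster_mode!r}")
        if self.leaflet not in ("inner", "outer", "both"):
            raise ValueError(f"unknown leaflet {self.leaflet!r}")
        if not (0 <= self.min_edge_pct <= 100):
            raise ValueError("min_edge_pct must be in [0, 100]")
        return self

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config, check it against the field schema, apply
    keyword overrides and validate."""
    data: dict = {}
    if path is not None:
        raw = yaml.safe_load(Path(path).read_text())
        if raw is None:
            raw = {}
        if not isinstance(raw, dict):
            raise ValueError(f"config root must be a mapping, got {type(raw).__name__}")
        data.update(raw)
    data.update({k: v for k, v in overrides.items() if v is not None})
    unknown = set(data) - set(_SCHEMA)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    for key, value in data.items():
        if not isinstance(value, _SCHEMA[key]):
            allowed = "/".join(t.__name__ for t in _SCHEMA[key])
            raise ValueError(
                f"config key {key!r}: expected {allowed}, got {type(value).__name__}"
            )
    return RunConfig(**data).validate()


def config_hash(config: RunConfig) -> str:
    return hashlib.sha256(
        json.dumps(config.to_dict(), sort_keys=True).encode()
    ).hexdigest()[:16]
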