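"""Analysis configuration: one document controlling every stage.

Unknown keys are rejected (typos must not silently fall back to defaults)
and every numeric setting is bounds-checked on construction.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["AnalysisConfig", "SelectionConfig", "VolumeConfig",
           "GeometryConfig", "ContactConfig"]


@dataclass
class SelectionConfig:
    group_map: dict[str, str] = field(default_factory=dict)  # residue prefix -> tag
    ring_residue: str = "CUR"
    radius_overrides: dict[str, float] = field(default_factory=dict)  # element -> nm


@dataclass
class VolumeConfig:
    probe_radii: tuple[float, ...] = (0.3, 0.4, 0.5, 0.6, 0.8)
    grid_spacing: float = 0.05  # nm
    window: float | None = None  # ns, last-N averaging window
    fit_degree: int = 1

    def __post_init__(self) -> None:
        if len(self.probe_radii) < 3:
            raise ValueError("need at least 3 probe radii")
        if self.grid_spacing <= 0:
            raise ValueError("grid_spacing must be positive")
        if self.fit_degree not in (1, 2):
            raise ValueError("fit_degree must be 1 (linear) or 2 (quadratic)")


@dataclass
class GeometryConfig:
    plateau_window: float = 20.0  # ns
    plateau_slope_tol: float = 0.002  # nm/ns
    cluster_cutoff: float = 0.45  # nm
    slab_thickness: float = 0.8  # nm
    map_grid: float = 0.1  # nm
    water_shell: float = 0.5  # nm

    def __post_init__(self) -> None:
        for name in ("plateau_window", "plateau_slope_tol", "cluster_cutoff",
                     "slab_thickness", "map_grid", "water_shell"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class ContactConfig:
    rdf_bin_width: float = 0.01  # nm
    rdf_r_max: float = 2.0  # nm
    stacking_d_max: float = 0.5  # nm
    stacking_angle_max: float = 30.0  # degrees
    contact_cutoff: float = 0.7  # nm, guest-host burial contact
    burial_interior: float = 0.9
    burial_aqueous: float = 0.1

    def __post_init__(self) -> None:
        if not 0 <= self.burial_aqueous < self.burial_interior <= 1:
            raise ValueError("burial thresholds must satisfy 0 <= aqueous < interior <= 1")
        for name in ("rdf_bin_width", "rdf_r_max", "stacking_d_max",
                     "stacking_angle_max", "contact_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")


@dataclass
class AnalysisConfig:
    selections: SelectionConfig = field(default_factory=SelectionConfig)
    volume: VolumeConfig = field(default_factory=VolumeConfig)
    geometry: GeometryConfig = field(default_factory=GeometryConfig)
    contacts: ContactConfig = field(default_factory=ContactConfig)
    seed: int = 0

    _SECTIONS = {"selections": SelectionConfig, "volume": VolumeConfig,
                 "geometry": GeometryConfig, "contacts": ContactConfig}

    @classmethod
    def from_dict(cls, data: dict) -> "AnalysisConfig":
        data = dict(data)
        kwargs: dict[str, object] = {}
        for section, section_cls in cls._SECTIONS.items():
            payload = data.pop(section, {})
            known = {f.name for f in dataclasses.fields(section_cls)}
            unknown = set(payload) - known
            if unknown:
                raise ValueError(
                    f"unknown key(s) in config section {section!r}: {sorted(unknown)}"
                )
            if "probe_radii" in payload:
                payload["probe_radii"] = tuple(payload["probe_radii"])
            kwargs[section] = section_cls(**payload)
        if "seed" in data:
            kwargs["seed"] = int(data.pop("seed"))
        if data:
            raise ValueError(f"unknown top-level config key(s): {sorted(data)}")
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_dict(self) -> dict:
        out = dataclasses.asdict(self)
        out["volume"]["probe_radii"] = list(out["volume"]["probe_radii"])
        return out

    def digest(self) -> str:
        """Stable hash of the configuration, for report provenance."""
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]
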