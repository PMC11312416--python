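"""Run configuration: YAML-serializable defaults reproducing the baseline study."""

from __future__ import annotations

import io
from dataclasses import asdict, dataclass, field, fields, replace
from pathlib import Path
from typing import Optional

import yaml

from .materials import (
    BalloonSpec,
    MaterialProperties,
    PVGeometry,
    build_domain,
    default_materials,
    default_perfusion,
    pv_parameters,
)
from .solver import SimulationConfig


@dataclass
class RunConfig:
    """Complete, serializable description of a simulation campaign.

    The defaults reproduce the baseline setup with no overrides: left
    superior PV, 23 x 20 mm balloon centered on the 60 mm vein, 10 mm
    pulmonary layer, Dirichlet thermocouple-schedule boundary, two cycles,
    30 s rewarm, lesion threshold -15 degC.
    """

    vein: str = "left superior"
    pulmonary_layer_thickness_mm: float = 10.0
    layer_order: tuple[str, str] = ("pulmonary_tissue", "vascular_wall")
    balloon: dict = field(default_factory=dict)          # BalloonSpec overrides
    material_overrides: dict = field(default_factory=dict)
    cell_size_mm: float = 0.15
    timestep_s: float = 0.1
    scheme: str = "implicit"
    boundary_mode: str = "dirichlet_schedule"
    latent_heat_enabled: bool = False
    snapshot_interval_s: float = 10.0
    rewarm_duration_s: float = 30.0
    cycles: int = 2
    lesion_threshold_C: float = -15.0
    display_threshold_C: float = 0.0
    therapy_log: Optional[str] = None      # None -> packaged five-patient table
    output_dir: str = "cryopvi_out"
    export_fields: bool = True

    def __post_init__(self) -> None:
        self.layer_order = tuple(self.layer_order)

    # -- component builders ----------------------------------------------
    def pv_geometry(self) -> PVGeometry:
        return pv_parameters(self.vein, self.pulmonary_layer_thickness_mm)

    def balloon_spec(self) -> BalloonSpec:
        pv = self.pv_geometry()
        kwargs = {"axial_center": pv.length / 2.0, **self.balloon}
        return BalloonSpec(**kwargs)

    def materials(self) -> dict[str, MaterialProperties]:
        mats = default_materials()
        for name, over in self.material_overrides.items():
            if name not in mats:
                raise KeyError(f"unknown material {name!r}")
            mats[name] = replace(mats[name], **over)
        return mats

    def build_domain(self):
        return build_domain(self.pv_geometry(), self.balloon_spec(),
                            resolution=self.cell_size_mm,
                            materials=self.materials(),
                            perfusion=default_perfusion(),
                            layer_order=self.layer_order)

    def solver_config(self) -> SimulationConfig:
        return SimulationConfig(
            timestep=self.timestep_s, cell_size_mm=self.cell_size_mm,
            scheme=self.scheme, boundary_mode=self.boundary_mode,
            latent_heat_enabled=self.latent_heat_enabled,
            snapshot_interval=self.snapshot_interval_s)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["layer_order"] = list(self.layer_order)
        return d

    def to_yaml(self, path: str | Path | None = None) -> str:
        text = yaml.safe_dump(self.to_dict(), sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, source: str | Path | io.IOBase) -> "RunConfig":
        if isinstance(source, io.IOBase):
            data = yaml.safe_load(source)
        elif isinstance(source, Path):
            data = yaml.safe_load(source.read_text())
        else:
            text = str(source)
            if "\n" not in text and Path(text).exists():
                text = Path(text).read_text()
            data = yaml.safe_load(text)
        return cls.from_dict(data or {})


def materials_to_yaml(materials: dict[str, MaterialProperties]) -> str:
    """Serialize a material library to YAML (SI units)."""
    return yaml.safe_dump({name: asdict(m) for name, m in materials.items()},
                          sort_keys=True)


def materials_from_yaml(text: str) -> dict[str, MaterialProperties]:
    data = yaml.safe_load(text)
    return {name: MaterialProperties(**d) for name, d in data.items()}
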