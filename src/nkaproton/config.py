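"""Pipeline configuration: thresholds, cutoffs, pathway geometry, I/O.

The config round-trips losslessly through YAML; every distance is in Å
and every threshold is strictly positive.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .metrics import StabilityThresholds
from .pathways import PathwayDefinition
from .states import BindingSiteRegistry, ResidueKey, default_registry

__all__ = ["ConfigError", "PipelineConfig"]


class ConfigError(ValueError):
    """Invalid or non-round-trippable configuration."""


@dataclass
class PipelineConfig:
    """All knobs of the analysis pipeline, with the study's defaults."""

    registry: BindingSiteRegistry = field(default_factory=default_registry)
    hydration_cutoff: float = 5.0   # Å, N_water counting
    escape_threshold: float = 5.0   # Å, unbinding displacement
    hydration_radius: float = 2.5   # Å, cluster residue selection
    shell_radius: float = 9.0       # Å, single-ion water shell
    carve_water_cutoff: float = 5.0  # Å, waters kept in the cluster model
    corridor_radius: float = 5.0    # Å, pathway corridors
    nwater_threshold: float = 8.0
    rmsf_threshold: float = 0.5     # Å
    open_baseline: float = 1.0      # transits/replica for an open gate
    release_tolerance: float = 5.0  # kcal/mol
    window: Optional[tuple[float, float]] = None  # ps; None = last 10 ns
    pathways: list[PathwayDefinition] = field(default_factory=list)
    seed: int = 0
    input_dir: Optional[str] = None
    output_dir: str = "results"

    def __post_init__(self) -> None:
        for name in ("hydration_cutoff", "escape_threshold", "hydration_radius",
                     "shell_radius", "carve_water_cutoff", "corridor_radius",
                     "nwater_threshold", "rmsf_threshold"):
            if getattr(self, name) <= 0:
                raise ConfigError(f"{name} must be positive")
        if self.release_tolerance < 0 or self.open_baseline < 0:
            raise ConfigError("baselines/tolerances must be >= 0")

    @property
    def thresholds(self) -> StabilityThresholds:
        return StabilityThresholds(nwater=self.nwater_threshold,
                                   rmsf=self.rmsf_threshold,
                                   escape=self.escape_threshold)

    # -- serialisation ------------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["registry"] = {
            "sites": [{"label": lab, "chain": glu.chain_id,
                       "glu": glu.residue_number, "asp": asp.residue_number}
                      for lab, glu, asp in self.registry.sites]}
        d["pathways"] = [{"name": p.name, "mouth": list(p.mouth_point),
                          "site": list(p.site_point),
                          "corridor_radius": p.corridor_radius,
                          "associated_site": p.associated_site}
                         for p in self.pathways]
        if self.window is not None:
            d["window"] = list(self.window)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        reg = d.pop("registry", None)
        if reg is not None:
            sites = tuple(
                (s["label"],
                 ResidueKey(s.get("chain", "A"), int(s["glu"]), "GLU"),
                 ResidueKey(s.get("chain", "A"), int(s["asp"]), "ASP"))
                for s in reg["sites"])
            d["registry"] = BindingSiteRegistry(sites=sites)
        paths = d.pop("pathways", None) or []
        d["pathways"] = [PathwayDefinition(p["name"], tuple(p["mouth"]),
                                           tuple(p["site"]),
                                           float(p.get("corridor_radius", 5.0)),
                                           p.get("associated_site", ""))
                         for p in paths]
        if d.get("window") is not None:
            d["window"] = tuple(float(x) for x in d["window"])
        try:
            return cls(**d)
        except TypeError as e:
            raise ConfigError(str(e)) from None

    def to_yaml(self, path) -> None:
        Path(path).write_text(
            yaml.safe_dump(self.to_dict(), sort_keys=True,
                           default_flow_style=False))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        try:
            data = yaml.safe_load(Path(path).read_text())
        except yaml.YAMLError as e:
            raise ConfigError(f"cannot parse config: {e}") from None
        if not isinstance(data, dict):
            raise ConfigError("config file must hold a mapping")
        return cls.from_dict(data)
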