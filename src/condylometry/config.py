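"""Pipeline configuration with strict key checking."""

from __future__ import annotations

from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Optional

from .errors import ConfigError
from .io import load_yaml


@dataclass
class PipelineConfig:
    """Resolved pipeline configuration.

    ``mode`` is ``"simulate"`` (tables drawn from the published group
    parameters) or ``"measure"`` (mesh + landmark files measured). Unknown
    keys in a YAML file are rejected.
    """

    mode: str = "simulate"
    schemes: list = field(default_factory=lambda: ["symmetry", "sagittal",
                                                   "vertical"])
    mesh_dir: Optional[str] = None
    landmarks_dir: Optional[str] = None
    table: Optional[str] = None
    out_dir: str = "condylometry_out"
    seed: int = 0
    n_boot: int = 1000
    f_enter: float = 3.84
    f_remove: float = 2.71
    priors: str = "proportional"
    depth_variant: str = "caliper"
    corr_threshold: float = 0.9
    log_level: str = "INFO"

    def validate(self) -> "PipelineConfig":
        if self.mode not in ("simulate", "measure"):
            raise ConfigError("mode must be 'simulate' or 'measure'")
        from .synthgen.params import SCHEMES
        for s in self.schemes:
            if s not in SCHEMES:
                raise ConfigError(f"unknown scheme {s!r}")
        if self.mode == "measure" and not (self.mesh_dir and self.landmarks_dir):
            raise ConfigError("measure mode needs mesh_dir and landmarks_dir")
        if self.priors not in ("proportional", "equal"):
            raise ConfigError("priors must be 'proportional' or 'equal'")
        if self.depth_variant not in ("caliper", "extent"):
            raise ConfigError("depth_variant must be 'caliper' or 'extent'")
        if self.n_boot < 10:
            raise ConfigError("n_boot must be >= 10")
        if not self.f_remove < self.f_enter:
            raise ConfigError("f_remove must be below f_enter")
        return self

    def as_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = load_yaml(path)
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(
                f"unknown configuration keys in {Path(path)}: "
                f"{sorted(unknown)}")
        return cls(**data).validate()
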