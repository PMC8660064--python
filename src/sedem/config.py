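"""Pipeline configuration (YAML/JSON-loadable, strict about unknown keys)."""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Mapping, Optional

import yaml

from .errors import ConfigError

SYSTEMS = ("odt", "classic", "both")


@dataclass(frozen=True)
class PipelineConfig:
    system: str = "odt"
    decimals: int = 2
    dissolution_correction: bool = True
    parameter_overrides: dict = field(default_factory=dict)
    output_dir: Optional[str] = None

    def __post_init__(self) -> None:
        if self.system not in SYSTEMS:
            raise ConfigError(f"system must be one of {SYSTEMS}, got {self.system!r}")
        if not isinstance(self.decimals, int) or self.decimals < 0:
            raise ConfigError(f"decimals must be a non-negative integer, got {self.decimals!r}")

    @property
    def systems(self) -> tuple[str, ...]:
        return ("odt", "classic") if self.system == "both" else (self.system,)

    @classmethod
    def from_dict(cls, data: Mapping) -> "PipelineConfig":
        known = {f.name for f in fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        data = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: expected a mapping at the top level")
        return cls.from_dict(data)
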