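"""Single-file pipeline configuration with per-stage sections.

The config round-trips to YAML or JSON. Unknown keys are rejected so a
typo cannot silently fall back to a default.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Any, Dict, Optional, Tuple

import yaml

from .candidates import EnumerationConfig
from .mining import MiningConfig
from .ms2 import AssignConfig
from .simulate import SimConfig

__all__ = ["Ms1Config", "PipelineConfig"]


@dataclass(frozen=True)
class Ms1Config:
    tol_ppm: float = 5.0
    scan_range: Tuple[float, float] = (500.0, 1700.0)


@dataclass
class PipelineConfig:
    mining: MiningConfig = field(default_factory=MiningConfig)
    enumeration: EnumerationConfig = field(default_factory=EnumerationConfig)
    ms1: Ms1Config = field(default_factory=Ms1Config)
    ms2: AssignConfig = field(default_factory=AssignConfig)
    sim: SimConfig = field(default_factory=SimConfig)
    output_dir: str = "."
    log_level: str = "INFO"

    def to_dict(self) -> Dict[str, Any]:
        def convert(value):
            if dataclasses.is_dataclass(value) and not isinstance(value, type):
                return {f.name: convert(getattr(value, f.name))
                        for f in fields(value)}
            if isinstance(value, tuple):
                return [convert(v) for v in value]
            if isinstance(value, frozenset):
                return sorted(value)
            return value

        return convert(self)

    @classmethod
    def from_dict(cls, data: Dict[str, Any]) -> "PipelineConfig":
        known = {f.name: f for f in fields(cls)}
        unknown = set(data) - set(known)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        kwargs: Dict[str, Any] = {}
        for name, f in known.items():
            if name not in data:
                continue
            value = data[name]
            if dataclasses.is_dataclass(f.type) or name in (
                    "mining", "enumeration", "ms1", "ms2", "sim"):
                section_cls = {"mining": MiningConfig,
                               "enumeration": EnumerationConfig,
                               "ms1": Ms1Config, "ms2": AssignConfig,
                               "sim": SimConfig}[name]
                kwargs[name] = _section_from_dict(section_cls, value, name)
            else:
                kwargs[name] = value
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        path = Path(path)
        text = path.read_text()
        data = (json.loads(text) if path.suffix.lower() == ".json"
                else yaml.safe_load(text)) or {}
        return cls.from_dict(data)

    def to_file(self, path) -> None:
        path = Path(path)
        data = self.to_dict()
        if path.suffix.lower() == ".json":
            path.write_text(json.dumps(data, indent=2) + "\n")
        else:
            path.write_text(yaml.safe_dump(data, sort_keys=False))

    def digest(self) -> str:
        """Short stable hash of the config, stamped into output headers."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]


def _section_from_dict(section_cls, value, name):
    if isinstance(value, section_cls):
        return value
    known = {f.name: f for f in fields(section_cls)}
    unknown = set(value) - set(known)
    if unknown:
        raise ValueError(f"unknown keys in config section {name!r}: {sorted(unknown)}")
    kwargs = {}
    for k, v in value.items():
        if isinstance(v, list):
            v = tuple(tuple(x) if isinstance(x, list) else x for x in v)
        kwargs[k] = v
    return section_cls(**kwargs)
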