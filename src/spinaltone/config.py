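"""Pipeline configuration: JSON round-trip, strict key validation."""
from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

from .trace import ParameterError


class ConfigError(ValueError):
    """Invalid pipeline configuration."""


@dataclass
class DetectionConfig:
    threshold_k: float = 4.0
    min_separation_ms: float = 5.0
    fit_window_fraction: float = 0.1


@dataclass
class BoundaryConfig:
    mixed_low_ms: float = 16.8
    mixed_high_ms: float = 35.7


@dataclass
class CalciumConfig:
    threshold_pct: float = 3.5
    burst_window_s: float = 300.0
    burst_min_peaks: int = 3
    min_separation_s: float = 2.0
    control_baseline_s: float = 30.0
    drug_baseline_s: float = 60.0
    drug_arrival_s: float = 60.0


@dataclass
class ScrnaConfig:
    threshold: float = 0.01
    direction: str = "greater"
    population_gene: str = "Grpr"


@dataclass
class PipelineConfig:
    """Everything a pipeline run needs besides the seed-derived randomness."""

    seed: int = 0
    output_dir: str = "spinaltone_out"
    generator_preset: str = "study_vc_ipsc"
    cell_preset: str = "study_cell"
    detection: DetectionConfig = field(default_factory=DetectionConfig)
    boundaries: BoundaryConfig = field(default_factory=BoundaryConfig)
    calcium: CalciumConfig = field(default_factory=CalciumConfig)
    scrna: ScrnaConfig = field(default_factory=ScrnaConfig)

    def to_dict(self) -> dict[str, Any]:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.to_dict(), indent=1, sort_keys=True)
        if path is not None:
            Path(path).write_text(text)
        return text

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:16]

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "PipelineConfig":
        return _build(cls, data, path="")

    @classmethod
    def from_json(cls, source: str | Path) -> "PipelineConfig":
        path = Path(source)
        try:
            text = path.read_text() if path.exists() else str(source)
            data = json.loads(text)
        except (json.JSONDecodeError, OSError) as exc:
            raise ConfigError(f"cannot parse config: {exc}") from exc
        return cls.from_dict(data)


_SUBCONFIGS = {
    "detection": DetectionConfig,
    "boundaries": BoundaryConfig,
    "calcium": CalciumConfig,
    "scrna": ScrnaConfig,
}


def _build(cls, data: dict[str, Any], path: str):
    """Instantiate a dataclass tree, rejecting unknown keys by name."""
    if not isinstance(data, dict):
        raise ConfigError(f"expected a mapping at {path or 'top level'}")
    fields = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - fields
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} at {path or 'top level'}"
        )
    kwargs = {}
    for name, value in data.items():
        sub = _SUBCONFIGS.get(name)
        if sub is not None:
            kwargs[name] = _build(sub, value, path=f"{path}{name}.")
        else:
            kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ParameterError) as exc:
        raise ConfigError(str(exc)) from exc
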