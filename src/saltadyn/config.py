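"""Scenario configuration: YAML schema, validation, provenance.

A scenario is a single YAML document with per-stage parameter blocks.  Every
parameter that influences a result is recorded back into the run manifest so
that any output file is traceable to the exact configuration (and seed) that
produced it.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path
from typing import Any

import yaml

from .phases import SegmentationConfig
from .synthio import EnergyModelParams, PunctaSceneParams, SaltatoryParams

__all__ = ["ScenarioConfig", "ConfigError", "load_config", "config_digest"]


class ConfigError(ValueError):
    """Invalid scenario configuration; the message names the offending keys."""


@dataclass
class ScenarioConfig:
    """Validated scenario: stage selection plus per-stage parameter blocks."""

    name: str = "scenario"
    seed: int = 0
    n_cells: int = 20
    stages: list[str] = field(
        default_factory=lambda: ["simulate", "phases", "ratiometry", "stats"]
    )
    saltatory: SaltatoryParams = field(default_factory=SaltatoryParams)
    energy: EnergyModelParams = field(default_factory=EnergyModelParams)
    puncta_scene: PunctaSceneParams = field(default_factory=PunctaSceneParams)
    segmentation: SegmentationConfig = field(default_factory=SegmentationConfig)

    KNOWN_STAGES = ("simulate", "phases", "ratiometry", "puncta", "profile", "stats")

    def __post_init__(self) -> None:
        bad = [s for s in self.stages if s not in self.KNOWN_STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}")
        if self.n_cells < 1:
            raise ConfigError("n_cells must be >= 1")

    def to_dict(self) -> dict[str, Any]:
        d = asdict(self)
        d["saltatory"] = asdict(self.saltatory)
        d["energy"] = asdict(self.energy)
        d["puncta_scene"] = asdict(self.puncta_scene)
        d["segmentation"] = asdict(self.segmentation)
        return d


_BLOCKS = {
    "saltatory": SaltatoryParams,
    "energy": EnergyModelParams,
    "puncta_scene": PunctaSceneParams,
    "segmentation": SegmentationConfig,
}
_SCALARS = ("name", "seed", "n_cells", "stages")


def _build_block(cls, block: dict, name: str):
    valid = {f.name for f in fields(cls)}
    unknown = sorted(set(block) - valid)
    if unknown:
        raise ConfigError(f"unknown key(s) in {name!r} block: {unknown}")
    # tuples arrive from YAML as lists
    coerced = {
        k: tuple(v) if isinstance(v, list) else v for k, v in block.items()
    }
    try:
        return cls(**coerced)
    except (TypeError, ValueError) as exc:
        raise ConfigError(f"invalid {name!r} block: {exc}") from exc


def load_config(path: str | Path, overrides: dict[str, Any] | None = None
                ) -> ScenarioConfig:
    """Load and validate a scenario YAML; CLI overrides win over the file."""
    raw = yaml.safe_load(Path(path).read_text())
    if raw is None:
        raw = {}
    if not isinstance(raw, dict):
        raise ConfigError("scenario file must contain a mapping")
    if overrides:
        raw = {**raw, **overrides}

    unknown = sorted(set(raw) - set(_SCALARS) - set(_BLOCKS))
    if unknown:
        raise ConfigError(f"unknown top-level key(s): {unknown}")

    kwargs: dict[str, Any] = {k: raw[k] for k in _SCALARS if k in raw}
    for name, cls in _BLOCKS.items():
        if name in raw:
            if not isinstance(raw[name], dict):
                raise ConfigError(f"{name!r} block must be a mapping")
            kwargs[name] = _build_block(cls, raw[name], name)
    return ScenarioConfig(**kwargs)


def config_digest(cfg: ScenarioConfig) -> str:
    """Stable sha256 of the fully resolved configuration."""
    payload = json.dumps(cfg.to_dict(), sort_keys=True, default=str)
    return hashlib.sha256(payload.encode()).hexdigest()
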