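"""Run configuration: defaults, YAML round-trip, and config hashing.

The configuration is a versioned, flat-by-section key-value file.  Unknown
keys are rejected (fail fast) so a typo never silently falls back to a
default.  Every artifact written by the CLI records the hash of the
configuration that produced it; equal hashes mean byte-identical reruns.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import os
from dataclasses import dataclass, field

import yaml

from .exceptions import ConfigError
from .levelset import EvolutionParams

__all__ = ["HmfConfig", "InitConfig", "ExperimentConfig", "RunConfig"]

SCHEMA_VERSION = 1


@dataclass(frozen=True)
class HmfConfig:
    """Denoising-stage settings: iteration count and flat-square element size."""

    n: int = 1
    se_size: int = 3
    growing: bool = False


@dataclass(frozen=True)
class InitConfig:
    """Initialization-stage settings (two-class mixture fit and mask cleanup)."""

    min_area: int = 50
    c0: float = 2.0
    dilation_margin: int = 2
    em_seed: int = 0
    em_tol: float = 1e-6
    em_max_iter: int = 200
    std_floor: float = 1e-4


@dataclass(frozen=True)
class ExperimentConfig:
    """Noise-sweep protocol: corruption fractions and replicates per level."""

    noise_levels: tuple[float, ...] = (0.0, 0.01, 0.03, 0.05, 0.07)
    replicates: int = 3


def _from_section(cls, data: dict, name: str):
    if not isinstance(data, dict):
        raise ConfigError(f"section {name!r} must be a mapping")
    names = {f.name for f in dataclasses.fields(cls)}
    unknown = set(data) - names
    if unknown:
        raise ConfigError(f"unknown keys in section {name!r}: {sorted(unknown)}")
    if "noise_levels" in data:
        data = {**data, "noise_levels": tuple(data["noise_levels"])}
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Everything a pipeline run depends on, serializable and hashable."""

    evolution: EvolutionParams = field(default_factory=EvolutionParams)
    hmf: HmfConfig = field(default_factory=HmfConfig)
    init: InitConfig = field(default_factory=InitConfig)
    experiment: ExperimentConfig = field(default_factory=ExperimentConfig)

    def to_dict(self) -> dict:
        d = {
            "schema_version": SCHEMA_VERSION,
            "evolution": dataclasses.asdict(self.evolution),
            "hmf": dataclasses.asdict(self.hmf),
            "init": dataclasses.asdict(self.init),
            "experiment": dataclasses.asdict(self.experiment),
        }
        d["experiment"]["noise_levels"] = list(self.experiment.noise_levels)
        return d

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        if not isinstance(data, dict):
            raise ConfigError("configuration must be a mapping")
        data = dict(data)
        version = data.pop("schema_version", SCHEMA_VERSION)
        if version != SCHEMA_VERSION:
            raise ConfigError(f"unsupported schema_version {version!r}")
        sections = {"evolution": EvolutionParams, "hmf": HmfConfig, "init": InitConfig, "experiment": ExperimentConfig}
        unknown = set(data) - set(sections)
        if unknown:
            raise ConfigError(f"unknown top-level keys: {sorted(unknown)}")
        kwargs = {
            name: _from_section(sec_cls, data.get(name, {}), name)
            for name, sec_cls in sections.items()
        }
        return cls(**kwargs)

    def to_yaml(self, path: str | os.PathLike) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data or {})

    def config_hash(self) -> str:
        """Short stable hash of the full configuration."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
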