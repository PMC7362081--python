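"""Run configuration: scale constants, stage boundaries, generator settings
and thresholds, serializable to/from YAML with strict key checking."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field, fields

import yaml

from .pipeline import StagePartition
from .synthetic import GeneratorConfig

__all__ = ["ScaleConfig", "RunConfig"]


@dataclass(frozen=True)
class ScaleConfig:
    """Scale/nondimensionalization constants for fractality conversion.

    The fractality degree of a fitted stage is f(alpha) solving
    sigma = lam*dt**(2/f-1) with sigma = mu*alpha**2/tau0.  The source data
    fix none of these magnitudes, so they are explicit configuration with
    unit defaults; tau0 = 1 h makes the nondimensional time numerically the
    time in hours.
    """

    lam: float = 1.0
    dt: float = 0.1
    tau0: float = 1.0
    alpha: float = 1.0
    v0: float = 1.0

    def __post_init__(self):
        if self.lam <= 0 or self.dt <= 0 or self.tau0 <= 0 or self.alpha <= 0:
            raise ValueError("lam, dt, tau0, alpha must be > 0")
        if self.dt == 1.0:
            raise ValueError("dt must differ from 1 (fractality inversion)")
        if self.v0 <= 0:
            raise ValueError("v0 must be > 0")


def _build(cls, data: dict, path: str):
    """Construct a (nested) dataclass from a dict, rejecting unknown keys."""
    allowed = {f.name for f in fields(cls)}
    unknown = set(data) - allowed
    if unknown:
        raise ValueError(
            f"unknown configuration key(s) {sorted(unknown)} under '{path}'"
        )
    return cls(**data)


@dataclass(frozen=True)
class RunConfig:
    """Full, reproducible description of a run.

    Serializable both ways; the hash of the canonical JSON form is stamped
    into every output file so results can be traced to their configuration.
    Unknown keys in a config file are rejected by name.
    """

    scale: ScaleConfig = field(default_factory=ScaleConfig)
    partition: StagePartition = field(default_factory=StagePartition)
    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    adequacy_threshold: float = 0.90
    cv_threshold: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if not (0 < self.adequacy_threshold <= 1):
            raise ValueError("adequacy_threshold must be in (0, 1]")
        if self.cv_threshold <= 0:
            raise ValueError("cv_threshold must be > 0")

    # -- serialization ----------------------------------------------------

    def to_dict(self) -> dict:
        return asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "RunConfig":
        data = dict(data)
        allowed = {f.name for f in fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown configuration key(s) {sorted(unknown)}")
        if "scale" in data:
            data["scale"] = _build(ScaleConfig, data["scale"], "scale")
        if "partition" in data:
            data["partition"] = _build(StagePartition, data["partition"], "partition")
        if "generator" in data:
            data["generator"] = _build(GeneratorConfig, data["generator"], "generator")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must contain a mapping")
        return cls.from_dict(data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    def config_hash(self) -> str:
        """12-hex-digit digest of the canonical JSON form."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:12]
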