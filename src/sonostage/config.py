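"""Run configuration: nested parameter blocks, strict key validation, hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

from .enhancement import EnhancementConfig
from .simulator import SimConfig
from .staging import StagingTrainConfig


class ConfigError(ValueError):
    pass


@dataclass
class DetectorTrainConfig:
    """How the frame-event detector is trained (from simulated nights)."""

    n_nights: int = 4
    night_epochs: int = 40
    max_frames_per_night: int = 60_000
    holdout_fraction: float = 0.2
    max_iter: int = 300


@dataclass
class FeatureConfig:
    breath_threshold: float = 0.5
    min_event_frames: int = 3


@dataclass
class ReportConfig:
    percent_denominator: str = "tst"       # "tst" | "recording"
    rem_merge_gap_epochs: int = 60
    rem_min_cluster_epochs: int = 2


@dataclass
class RunConfig:
    """Top-level configuration; unknown keys are rejected, and the canonical
    JSON hash is embedded in every output file."""

    seed: int = 0
    log_level: str = "INFO"
    enhancement: EnhancementConfig = field(default_factory=EnhancementConfig)
    detector: DetectorTrainConfig = field(default_factory=DetectorTrainConfig)
    features: FeatureConfig = field(default_factory=FeatureConfig)
    staging: StagingTrainConfig = field(default_factory=StagingTrainConfig)
    report: ReportConfig = field(default_factory=ReportConfig)
    simulator: SimConfig = field(default_factory=SimConfig)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _build(cls, data: dict, path: str):
    if not isinstance(data, dict):
        raise ConfigError(f"{path or 'config'}: expected a mapping")
    fields = {f.name: f for f in dataclasses.fields(cls)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ConfigError(
            f"unknown config key(s) {sorted(unknown)} under '{path or 'root'}'")
    kwargs = {}
    for name, value in data.items():
        ftype = fields[name].type
        target = _NESTED.get((cls, name))
        if target is not None:
            kwargs[name] = _build(target, value, f"{path}.{name}" if path else name)
        else:
            if isinstance(value, list):
                value = tuple(value)
            kwargs[name] = value
    return cls(**kwargs)


_NESTED = {
    (RunConfig, "enhancement"): EnhancementConfig,
    (RunConfig, "detector"): DetectorTrainConfig,
    (RunConfig, "features"): FeatureConfig,
    (RunConfig, "staging"): StagingTrainConfig,
    (RunConfig, "report"): ReportConfig,
    (RunConfig, "simulator"): SimConfig,
}


def load_config(path=None, overrides: dict | None = None) -> RunConfig:
    """Load a YAML run configuration (missing file fields take defaults)."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    if overrides:
        data = _deep_merge(data, overrides)
    return _build(RunConfig, data, "")


def _deep_merge(base: dict, extra: dict) -> dict:
    out = dict(base)
    for k, v in extra.items():
        if isinstance(v, dict) and isinstance(out.get(k), dict):
            out[k] = _deep_merge(out[k], v)
        else:
            out[k] = v
    return out
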