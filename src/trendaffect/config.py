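"""Pipeline configuration: nested dataclasses with strict YAML/JSON I/O.

Unknown keys are rejected (typos should fail loudly, not silently fall
back to defaults), and a loaded configuration round-trips through
serialization unchanged.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field

import yaml

__all__ = ["PipelineConfig", "load_config", "config_sha"]


@dataclass
class TrendsSection:
    n_words: int = 1000
    n_coupled_pos: int = 30
    n_coupled_neg: int = 30
    coupling_strength: float = 0.9
    noise_sd: float = 4.0
    seasonal_amplitude: float = 8.0


@dataclass
class SelectionSection:
    group_size: int = 20
    tail_fraction: float = 0.025
    primary_min_measures: int = 3
    fallback_min_measures: int = 2
    allowed_pos: list = field(default_factory=lambda: ["noun", "verb"])
    pos_filter_first: bool = True


@dataclass
class RatingsSection:
    n_participants: int = 71
    vpc_participant: float = 0.10
    vpc_word: float = 0.15
    vpc_residual: float = 0.75
    total_sd: float = 1.5
    split_half_randomizations: int = 10_000


@dataclass
class LexicalSection:
    measure: str = "z_spear"
    tolerance_cutoff: float = 0.6
    entry_p: float = 0.05
    removal_p: float = 0.10


@dataclass
class PowerSection:
    alpha: float = 0.05
    target_power: float = 0.80
    rm_correlation: float = 0.80


@dataclass
class PipelineConfig:
    seed: int = 0
    trends: TrendsSection = field(default_factory=TrendsSection)
    selection: SelectionSection = field(default_factory=SelectionSection)
    ratings: RatingsSection = field(default_factory=RatingsSection)
    lexical: LexicalSection = field(default_factory=LexicalSection)
    power: PowerSection = field(default_factory=PowerSection)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, data: dict) -> "PipelineConfig":
        return _build(cls, data or {}, path="")

    def to_yaml(self) -> str:
        return yaml.safe_dump(self.to_dict(), sort_keys=True)


def _build(dc_type, data: dict, path: str):
    if not isinstance(data, dict):
        raise ValueError(f"config section {path or '<root>'} must be a mapping")
    fields = {f.name: f for f in dataclasses.fields(dc_type)}
    unknown = set(data) - set(fields)
    if unknown:
        raise ValueError(
            f"unknown config key(s) {sorted(unknown)} under "
            f"{path or '<root>'}"
        )
    kwargs = {}
    for name, f in fields.items():
        if name not in data:
            continue
        if dataclasses.is_dataclass(f.type) or (
                isinstance(f.type, str) and f.type.endswith("Section")):
            sub_type = f.default_factory() .__class__ if f.default_factory \
                is not dataclasses.MISSING else f.type
            kwargs[name] = _build(sub_type, data[name],
                                  path=f"{path}.{name}".lstrip("."))
        else:
            kwargs[name] = data[name]
    return dc_type(**kwargs)


def load_config(path) -> PipelineConfig:
    """Load YAML (or JSON — valid YAML) into a validated PipelineConfig."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return PipelineConfig.from_dict(data or {})


def config_sha(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]
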