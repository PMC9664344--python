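"""Run configuration: every tunable of the pipeline in one YAML-serializable object."""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import yaml

__all__ = ["RunConfig", "MarkerOptions", "CompositionOptions", "CompetitionOptions"]


@dataclass
class MarkerOptions:
    linkage: str = "average"
    min_mean_r: float = 0.5
    fdr_threshold: float = 0.01


@dataclass
class CompositionOptions:
    pseudocount: float = 0.0
    exact_test_cap: int = 30


@dataclass
class CompetitionOptions:
    allow_fraction_scale: bool = False
    td_mode: str = "regression"  # or "endpoint"


@dataclass
class RunConfig:
    """Full pipeline configuration; round-trips through YAML unchanged."""

    seed: int = 0
    out_dir: str = "."
    markers: MarkerOptions = field(default_factory=MarkerOptions)
    composition: CompositionOptions = field(default_factory=CompositionOptions)
    competition: CompetitionOptions = field(default_factory=CompetitionOptions)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        for key, sub in (("markers", MarkerOptions),
                         ("composition", CompositionOptions),
                         ("competition", CompetitionOptions)):
            if key in d and isinstance(d[key], dict):
                d[key] = sub(**d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})
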