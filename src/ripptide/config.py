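"""Pipeline configuration: one serializable object for every knob."""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass


@dataclass
class PipelineConfig:
    # genome mining
    window: int = 10_000
    evalue_threshold: float = 1e-5
    min_orf_aa: int = 11
    max_orf_aa: int = 200
    # cores
    min_core_aa: int = 3
    max_core_aa: int = 30
    cleavage_k: int = 5
    core_strategies: tuple = ("exhaustive",)   # exhaustive | repeat | neural
    repeat_trigger_profiles: tuple = ("TIGR03604", "PF00881")  # YcaO-like
    # enumeration
    enumeration_cap: int = 2 ** 16
    # spectral search
    fragmentation_depth: int = 2
    precursor_tol: float = 0.02
    fragment_tol: float = 0.02
    # misc
    seed: int = 0

    def validate(self):
        for name in ("window", "min_orf_aa", "max_orf_aa", "min_core_aa",
                     "max_core_aa", "cleavage_k", "enumeration_cap",
                     "fragmentation_depth"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        for name in ("evalue_threshold", "precursor_tol", "fragment_tol"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")

    def to_json(self) -> str:
        return json.dumps(asdict(self), indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "PipelineConfig":
        data = json.loads(text)
        for key in ("core_strategies", "repeat_trigger_profiles"):
            if key in data:
                data[key] = tuple(data[key])
        return cls(**data)

    @classmethod
    def load(cls, path) -> "PipelineConfig":
        text = open(path).read()
        if str(path).endswith((".yml", ".yaml")):
            import yaml
            data = yaml.safe_load(text)
            return cls.from_json(json.dumps(data))
        return cls.from_json(text)
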