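"""Analysis configuration: defaults, YAML round-trip, provenance helpers."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .mediation import AnalysisSettings


@dataclass(frozen=True)
class AnalysisConfig:
    """Everything an ``analyze`` run needs; every field has a default."""

    input: str | None = None
    columns: dict = field(default_factory=dict)
    mediator_higher_is_worse: bool = True
    outcome_higher_is_better: bool = True
    alpha: float = 0.05
    mc_draws: int = 10_000
    seed: int = 0
    output_dir: str = "."

    def settings(self) -> AnalysisSettings:
        return AnalysisSettings(
            alpha=self.alpha, mc_draws=self.mc_draws, seed=self.seed
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, payload: dict) -> "AnalysisConfig":
        unknown = set(payload) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise ValueError(f"unknown config field(s): {sorted(unknown)}")
        return cls(**payload)

    @classmethod
    def from_yaml(cls, path) -> "AnalysisConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh) or {})

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    def digest(self) -> str:
        """Stable hash of the configuration, for run provenance."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def file_fingerprint(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()[:16]
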