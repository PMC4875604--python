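"""Run configuration: the protocol's constants, all overridable.

Defaults are the published protocol settings: 20 % hit threshold, x100
matrix scaling, 80 % high-confidence binding-score fraction with a 100-peak
minimum per TF, a 1,000,000 training-pair cap per matrix, a 70 % reliability
(PPV/NPV) threshold for aggregation, and 20 bp variant flanks.
"""

from __future__ import annotations

from dataclasses import dataclass, fields, replace
from pathlib import Path

import yaml


@dataclass(frozen=True)
class RunConfig:
    threshold_percent: float = 20.0
    scale: float = 100.0
    high_confidence_fraction: float = 0.8
    min_instances: int = 100
    pair_cap: int = 1_000_000
    min_predictive_value: float = 0.70
    flank: int = 20
    floor_fraction: float = 0.01
    holdout_fraction: float = 0.2
    seed: int = 0
    peak_dialect: str = "bed5"
    genome_build: str = "unknown"

    @classmethod
    def from_file(cls, path, **overrides) -> "RunConfig":
        """Load key-value YAML config; keyword overrides win over the file."""
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        raw.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**raw)

    def with_overrides(self, **overrides) -> "RunConfig":
        return replace(self, **{k: v for k, v in overrides.items() if v is not None})
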