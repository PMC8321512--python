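"""Pipeline run configuration: a versioned YAML schema.

A run config selects stages and carries every threshold the analysis uses
(mutation-rate filter 0.04, OR exclusivity cutoff 0.5, significance gate
0.05, CpG SD cutoff 0.27, log2 fold-change cutoff 0.585), a seed, input
paths and an output prefix. Unknown keys are rejected so typos fail loudly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields
from pathlib import Path
from typing import Any

import yaml

SCHEMA_VERSION = 1

#: Stages in dependency order.
STAGES = ("binarize", "table", "screen", "methyl", "de_threshold", "overlap")


class ConfigError(ValueError):
    """A run config violates the schema."""


@dataclass
class RunConfig:
    """Validated pipeline configuration."""

    schema_version: int = SCHEMA_VERSION
    stages: list[str] = field(default_factory=list)
    seed: int = 0
    out_prefix: str = "mutexm_run"

    # thresholds
    min_rate: float = 0.04
    or_max: float = 0.5
    or_cooccur_min: float = 2.0
    p_max: float = 0.05
    sd_min: float = 0.27
    lfc: float = 0.585
    q_max: float = 0.05
    k_clusters: int = 2

    # inputs (paths; only those needed by the selected stages are required)
    calls: str | None = None
    cohort: str | None = None
    matrix: str | None = None
    anchors: str | None = None
    beta: str | None = None
    groups: str | None = None
    control: str | None = None
    de_table: str | None = None
    set_a: str | None = None
    set_b: str | None = None
    universe: str | None = None
    counts: dict[str, int] | None = None  # n_total, n_a, n_b, n_both

    def __post_init__(self) -> None:
        if self.schema_version != SCHEMA_VERSION:
            raise ConfigError(
                f"unsupported schema_version {self.schema_version} "
                f"(expected {SCHEMA_VERSION})"
            )
        bad = [s for s in self.stages if s not in STAGES]
        if bad:
            raise ConfigError(f"unknown stage(s): {bad}; valid: {list(STAGES)}")
        if not 0 <= self.min_rate < 1:
            raise ConfigError(f"min_rate out of range [0, 1): {self.min_rate}")
        if not 0 < self.or_max < self.or_cooccur_min:
            raise ConfigError(
                f"need 0 < or_max < or_cooccur_min, got {self.or_max} / "
                f"{self.or_cooccur_min}"
            )
        if not 0 < self.p_max <= 1:
            raise ConfigError(f"p_max out of range (0, 1]: {self.p_max}")
        if self.sd_min < 0:
            raise ConfigError(f"sd_min must be non-negative: {self.sd_min}")
        if self.lfc <= 0:
            raise ConfigError(f"lfc must be positive: {self.lfc}")
        if self.k_clusters < 1:
            raise ConfigError(f"k_clusters must be >= 1: {self.k_clusters}")

    @classmethod
    def from_dict(cls, data: dict[str, Any]) -> "RunConfig":
        allowed = {f.name for f in dc_fields(cls)}
        unknown = set(data) - allowed
        if unknown:
            raise ConfigError(f"unknown config key(s): {sorted(unknown)}")
        return cls(**data)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        data = yaml.safe_load(Path(path).read_text())
        if not isinstance(data, dict):
            raise ConfigError(f"{path}: config must be a YAML mapping")
        return cls.from_dict(data)

    def to_dict(self) -> dict[str, Any]:
        return {f.name: getattr(self, f.name) for f in dc_fields(self)}
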