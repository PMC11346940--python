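"""Run configuration: thresholds, vocabularies, file paths, seed.

Defaults equal the study conditions: quasi H threshold 150, Wilcoxon alpha
0.05, |log2FC| >= 1, prevalence >= 5%, response >= 50% in >= 1/9 panels,
GI50 class ceilings at 1 nM and 10 nM, cluster counts 5/10/10.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cascade import CRITICAL_TISSUES
from .combos import DEFAULT_PANEL_MAPPING, DEFAULT_PAYLOADS
from .io import ConfigError, NCI60_PANELS

__all__ = ["RunConfig", "load_config"]


def _default_cluster_counts() -> dict:
    return {"picomolar_only": 5, "low_nanomolar_only": 10, "overlap": 10}


def _default_synth() -> dict:
    return {
        "n_genes": 500,
        "n_cancer_types": 20,
        "n_tissues": 44,
        "n_ideal": 10,
        "decoy_family_size": 5,
        "samples_per_cohort": 30,
        "mutation_cohorts": ["LUAD", "BRCA", "PAAD", "THCA"],
        "mutation_samples_per_cohort": 200,
        "planted_associations": [
            ["T00001", "Q00001", "LUAD", 2.13, 0.20],
            ["T00001", "Q00002", "LUAD", 1.38, 0.15],
            ["T00002", "Q00003", "BRCA", -2.17, 0.30],
            ["T00003", "Q00004", "THCA", 1.50, 0.25],
        ],
        "n_compounds": 3000,
        "payload_groups": {
            "pico_only": 33,
            "nano_only": 631,
            "overlap": 65,
            "failed_pico": 93,
            "failed_nano": 1616,
        },
        "n_duplicate_pairs": 5,
    }


@dataclass
class RunConfig:
    seed: int = 0
    out_dir: str = "results"
    quasi_h_threshold: float = 150.0
    consistency_policy: str = "within_one"
    alpha: float = 0.05
    min_abs_log2fc: float = 1.0
    min_prevalence: float = 0.05
    min_group_size: int = 3
    response_threshold_pct: float = 50.0
    cluster_counts: dict = field(default_factory=_default_cluster_counts)
    critical_tissues: list = field(default_factory=lambda: list(CRITICAL_TISSUES))
    panels: list = field(default_factory=lambda: list(NCI60_PANELS))
    panel_mapping: dict = field(
        default_factory=lambda: {k: list(v) for k, v in DEFAULT_PANEL_MAPPING.items()}
    )
    payloads: list = field(default_factory=lambda: list(DEFAULT_PAYLOADS))
    inputs: dict = field(default_factory=dict)
    synth: dict = field(default_factory=_default_synth)

    def validate(self) -> None:
        if not 0.0 <= self.quasi_h_threshold <= 300.0:
            raise ConfigError(
                f"quasi_h_threshold {self.quasi_h_threshold} outside [0, 300]"
            )
        if self.consistency_policy not in ("within_one", "exact"):
            raise ConfigError(f"unknown consistency_policy {self.consistency_policy!r}")
        if not 0.0 < self.alpha < 1.0:
            raise ConfigError(f"alpha {self.alpha} outside (0, 1)")
        if self.min_abs_log2fc < 0.0:
            raise ConfigError("min_abs_log2fc must be >= 0")
        if not 0.0 <= self.min_prevalence <= 1.0:
            raise ConfigError(f"min_prevalence {self.min_prevalence} outside [0, 1]")
        if self.min_group_size < 1:
            raise ConfigError("min_group_size must be >= 1")
        if not 0.0 <= self.response_threshold_pct <= 100.0:
            raise ConfigError(
                f"response_threshold_pct {self.response_threshold_pct} outside [0, 100]"
            )
        if not self.panels:
            raise ConfigError("panel vocabulary must be non-empty")
        for group, k in self.cluster_counts.items():
            if int(k) < 1:
                raise ConfigError(f"cluster count for {group!r} must be >= 1")
        if not self.critical_tissues:
            raise ConfigError("critical_tissues must be non-empty")
        if self.seed < 0:
            raise ConfigError("seed must be non-negative")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load YAML config (all keys optional); keyword overrides win over file values."""
    data: dict = {}
    if path is not None:
        with Path(path).open("r", encoding="utf-8") as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigError(f"config file {path} must contain a mapping")
    known = {f.name for f in fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    cfg = RunConfig(**data)
    cfg.validate()
    return cfg
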