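"""Pipeline configuration: thresholds, seeds, and stage paths."""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All tunable thresholds, defaulting to the published constants."""

    seed: int = 0
    maf_floor: float = 0.05
    window_bp: int = 1_000_000
    corr_alpha: float = 0.05
    accept_fraction: float = 0.7
    max_cluster_size: int = 50
    susie_L: int = 10
    purity: float = 0.5
    coverage: float = 0.95
    coloc_threshold: float = 0.75
    q_threshold: float = 0.05
    near_tss_bp: int = 250
    n_permutations: int = 1000
    coloc_p1: float = 1e-4
    coloc_p2: float = 1e-4
    coloc_p12: float = 5e-6
    gwas_prior_sd: float = 0.15
    tissue: str = "synthetic"
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        checks = [
            (0.0 <= self.maf_floor <= 0.5, f"maf_floor must be in [0, 0.5], got {self.maf_floor}"),
            (self.window_bp > 0, "window_bp must be positive"),
            (0 < self.corr_alpha < 1, "corr_alpha must be in (0, 1)"),
            (0 < self.accept_fraction <= 1, "accept_fraction must be in (0, 1]"),
            (self.max_cluster_size >= 2, "max_cluster_size must be >= 2"),
            (self.susie_L >= 1, "susie_L must be >= 1"),
            (0 <= self.purity <= 1, "purity must be in [0, 1]"),
            (0 < self.coverage <= 1, "coverage must be in (0, 1]"),
            (0 < self.coloc_threshold <= 1, "coloc_threshold must be in (0, 1]"),
            (0 < self.q_threshold < 1, "q_threshold must be in (0, 1)"),
            (self.n_permutations >= 1, "n_permutations must be >= 1"),
        ]
        for ok, msg in checks:
            if not ok:
                raise ValueError(msg)

    def hash(self) -> str:
        payload = json.dumps(asdict(self), sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)
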