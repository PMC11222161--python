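"""Pipeline configuration: thresholds, bin sizes, seeds, condition labels.

Every threshold is echoed into output metadata by the pipeline writers so
results stay auditable; unknown configuration keys are rejected rather than
ignored (the many exclusion rules make silent misconfiguration dangerous).
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, fields
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    seed: int = 0
    outdir: str = "results/pipeline"
    condition: str = "bmp_m1"

    bin_size_genome: int = 10_000   # genome-wide tables
    bin_size_ko: int = 2_000        # WT/KO comparison

    min_depth: int = 4              # per-site depth for per-site averaging
    min_cpgs: int = 4               # qualifying CpGs per bin
    min_calls: int = 10             # pooled-call minimum

    escapee_level_threshold: float = 50.0
    escapee_max_gap_bins: int = 1
    escapee_min_bins: int = 3

    ko_delta: float = 30.0
    er_min_fold: float = 2.0
    er_demeth_fraction: float = 0.5
    expression_cutoff: float = 3.0  # on log2(RPM + 1)
    mark_high_threshold: float = 1.0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return asdict(self)
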