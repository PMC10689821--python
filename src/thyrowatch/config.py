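"""Run configuration: YAML-loadable settings plus a content hash.

Every output file produced by a run carries the SHA-256 hash of its
resolved configuration (header comment in CSVs, ``_meta`` entry in JSON)
so results remain traceable to the exact settings that produced them.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .hr_windows import CoverageRule
from .model import ModelConfig
from .thyroid import ReferenceRanges

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    """Settings of one evaluation run."""

    tft_path: str | None = None
    sleep_path: str | None = None
    sleep_format: str = "csv"  # "csv" per-sample rows | "json" pre-aggregated
    out_dir: str = "report"
    n_days: int = 10
    include_anchor_morning: bool = False
    min_nights: int = 3
    min_samples: int = 300
    step_days: int = 7
    log_tsh_interpolation: bool = False
    threshold: float = 0.5
    seed: int = 0
    tsh_floor: float = 0.025
    jsd_base: str = "e"
    ranges: dict = field(
        default_factory=lambda: {"ft4_low": 0.89, "ft4_high": 1.78, "tsh_low": 0.3, "tsh_high": 4.0}
    )
    model: dict = field(default_factory=dict)

    def coverage(self) -> CoverageRule:
        return CoverageRule(min_nights=self.min_nights, min_samples=self.min_samples)

    def reference_ranges(self) -> ReferenceRanges:
        return ReferenceRanges(**self.ranges)

    def model_config(self) -> ModelConfig:
        return ModelConfig(**self.model)

    def to_dict(self) -> dict:
        return asdict(self)

    def config_hash(self) -> str:
        # the output location is bookkeeping, not part of the experiment
        payload = {k: v for k, v in self.to_dict().items() if k != "out_dir"}
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Build a RunConfig from an optional YAML file plus keyword overrides."""
    data: dict = {}
    if path is not None:
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
    unknown = set(data) - set(RunConfig.__dataclass_fields__)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    data.update({k: v for k, v in overrides.items() if v is not None})
    return RunConfig(**data)
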