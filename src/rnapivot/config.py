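"""Run configuration: one YAML-serialisable object carrying every threshold.

Reports are self-describing: each TSV header names the tool version and a
hash of the configuration that produced it, so a report can always be traced
to the exact thresholds used.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .pivot_detection import DetectionConfig

__all__ = ["RunConfig", "load_config", "save_config"]


@dataclass
class RunConfig:
    """Inputs, thresholds and options of one analysis run."""

    input_a: str = ""
    input_b: str = ""
    format: str = "auto"
    chains: list[str] = field(default_factory=list)   # empty -> auto rRNA selection
    min_chain_length: int = 100
    numbering_map: str = ""
    stem_catalog: str = ""
    catalog_numbering: str = "author"
    metric: str = "per_residue_backbone_mean"
    min_atom_pairs: int = 30
    max_cycles: int = 5
    reject_sigma: float = 2.0
    pivot_threshold: float | None = None
    persistence: int = 2
    reporting_floor: float | None = None
    mobility_threshold: float | None = None
    min_run_length: int = 3
    contact_cutoff: float = 5.0
    amplification_factor: float = 1.5
    seed: int = 0
    output_dir: str = "."

    def __post_init__(self) -> None:
        positive = {
            "min_atom_pairs": self.min_atom_pairs,
            "reject_sigma": self.reject_sigma,
            "persistence": self.persistence,
            "contact_cutoff": self.contact_cutoff,
            "amplification_factor": self.amplification_factor,
            "min_run_length": self.min_run_length,
        }
        for name, value in positive.items():
            if value <= 0:
                raise ValueError(f"{name} must be positive, got {value}")
        for name in ("pivot_threshold", "reporting_floor", "mobility_threshold"):
            value = getattr(self, name)
            if value is not None and value <= 0:
                raise ValueError(f"{name} must be positive when set, got {value}")

    def detection(self) -> DetectionConfig:
        return DetectionConfig(
            metric=self.metric,
            min_atom_pairs=self.min_atom_pairs,
            max_cycles=self.max_cycles,
            reject_sigma=self.reject_sigma,
            pivot_threshold=self.pivot_threshold,
            persistence=self.persistence,
            reporting_floor=self.reporting_floor,
            mobility_threshold=self.mobility_threshold,
            min_run_length=self.min_run_length,
        )

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def load_config(path: str | Path) -> RunConfig:
    with open(path) as fh:
        data = yaml.safe_load(fh) or {}
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**data)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=True)
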