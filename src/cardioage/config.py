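"""Run configuration: one file (YAML or JSON) pins every switch a run
depends on, and its hash is echoed into every output, so each number in a
report is traceable to an explicit configuration."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional

import yaml

from .errors import ExperimentConfig
from .model import DEFAULT_PROFILE


@dataclass
class RunConfig:
    """Configuration of one end-to-end run.

    ``cohort`` holds CohortSpec overrides (counts, ages) plus the optional
    keys ``correlation_pairs`` (list of [var1, var2, r] triples; unspecified
    pairs are zero) and ``calibrate``; set ``generate_cohort`` false to skip
    the data stages entirely (fixture-driven reports need no cohort).
    """

    seed: int = 0
    output_dir: str = "run"
    generate_cohort: bool = True
    cohort: dict = field(default_factory=dict)
    cohort_path: Optional[str] = None       # load instead of generate
    screen_k: int = 6
    model_source: str = "fixture"           # "fixture" | "screened"
    profile: str = DEFAULT_PROFILE
    increment_rule: str = "unit"
    trajectory_mode: str = "recurrence"     # "recurrence" | "external"
    trajectory_path: Optional[str] = None
    ab2_start: str = "rk4"
    ab2_variant: str = "standard"
    reference: str = "integral"
    coefficient_mode: str = "signed"
    a0: float = 0.0

    def __post_init__(self) -> None:
        if self.model_source not in ("fixture", "screened"):
            raise ValueError(f"unknown model_source {self.model_source!r}")
        if self.trajectory_mode not in ("recurrence", "external"):
            raise ValueError(
                f"unknown trajectory_mode {self.trajectory_mode!r}")
        if self.trajectory_mode == "external" and not self.trajectory_path:
            raise ValueError("trajectory_mode='external' needs "
                             "trajectory_path")

    def experiment_config(self) -> ExperimentConfig:
        return ExperimentConfig(
            profile=self.profile,
            increment_rule=self.increment_rule,
            ab2_start=self.ab2_start,
            ab2_variant=self.ab2_variant,
            reference=self.reference,
            coefficient_mode=self.coefficient_mode,
            a0=self.a0,
            trajectory_path=(self.trajectory_path
                             if self.trajectory_mode == "external" else None),
        )

    def to_dict(self) -> dict:
        return asdict(self)

    def canonical_json(self) -> str:
        """Canonical form: every switch that affects results.  The output
        location is deliberately excluded so identical runs hash identically
        wherever they are written."""
        data = self.to_dict()
        data.pop("output_dir")
        return json.dumps(data, sort_keys=True, indent=2)

    def hash(self) -> str:
        return hashlib.sha256(self.canonical_json().encode()).hexdigest()[:16]

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        if not isinstance(data, dict):
            raise ValueError(f"config file {path} must hold a mapping")
        return cls(**data)
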