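"""Run configuration: every distribution parameter and analysis switch.

Defaults are the study conditions: 100 taxa with log-abundances
Normal(12.5, 2.5), 10 + 10 subjects, subject deviation sd 0.5 on the log
scale, 25% temporal noise, sequencing depth Normal(50000, 10000), CLR
pseudocount 0.5, Kruskal–Wallis on between-timepoint changes with BH
cutoff 0.1, and PERMANOVA on the post-intervention samples.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from . import community, dda, normalization, sequencing


@dataclass
class SimulationConfig:
    n_taxa: int = community.DEFAULT_N_TAXA
    log_mean: float = community.DEFAULT_LOG_MEAN
    log_sd: float = community.DEFAULT_LOG_SD
    subject_log_sd: float = community.DEFAULT_SUBJECT_LOG_SD
    n_per_group: int = 10
    noise_fraction: float = community.DEFAULT_NOISE_FRACTION
    log_symmetric_noise: bool = False

    depth_mean: float = sequencing.DEFAULT_DEPTH_MEAN
    depth_sd: float = sequencing.DEFAULT_DEPTH_SD

    pseudocount: float = normalization.DEFAULT_PSEUDOCOUNT
    alpha: float = dda.DEFAULT_ALPHA
    response_mode: str = dda.CHANGE
    change_scale: str = dda.LOG_RATIO
    rate_convention: str = dda.HALF_CLASS

    effect_sizes: tuple[float, ...] = community.EFFECT_SIZES
    proportions: tuple[float, ...] = community.PROPORTIONS
    n_iterations: int = 100

    methods: tuple[str, ...] = normalization.METHODS
    run_permanova: bool = True
    n_permutations: int = 0  # R² needs no permutations; >0 adds p-values

    def design(self) -> community.CohortDesign:
        return community.default_design(self.n_per_group)

    def grid(self, direction_regime: str) -> list[community.ScenarioSpec]:
        return [
            community.ScenarioSpec(direction_regime, e, p)
            for e in self.effect_sizes
            for p in self.proportions
        ]

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def from_dict(cls, data: dict) -> "SimulationConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        coerced = dict(data)
        for key in ("effect_sizes", "proportions", "methods"):
            if key in coerced:
                coerced[key] = tuple(coerced[key])
        return cls(**coerced)

    @classmethod
    def from_file(cls, path: str | Path) -> "SimulationConfig":
        """Load overrides from a JSON or YAML key-value file."""
        text = Path(path).read_text()
        data = yaml.safe_load(text) or {}
        return cls.from_dict(data)
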