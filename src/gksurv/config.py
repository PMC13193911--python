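"""Run configuration: one validated, serializable object per pipeline run.

A run is fully described by where its cohort comes from (a file or the
synthetic generator), the predictor specification, the hyperparameter grid,
the validation layout, the evaluation horizons, the dose grid and utility,
and the seeds.  The resolved configuration is embedded into every output
artifact so a report can always be traced back to the exact run that
produced it.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any, Optional

import yaml

from .forest import DEFAULT_TUNING_GRID, Hyperparams
from .synthetic import GeneratorParams

__all__ = ["RunConfig", "load_config"]

#: Compact default grid used by the command-line pipeline; the full
#: :data:`gksurv.forest.DEFAULT_TUNING_GRID` can be requested explicitly
#: with ``hyperparameter_grid: full``.
COMPACT_GRID: list[Hyperparams] = [
    Hyperparams(n_trees=200, max_depth=3, min_samples_leaf=5, min_samples_split=10, max_features=0.33),
    Hyperparams(n_trees=200, max_depth=5, min_samples_leaf=3, min_samples_split=6, max_features=0.58),
    Hyperparams(n_trees=200, max_depth=None, min_samples_leaf=10, min_samples_split=20, max_features=0.58),
]


@dataclass
class RunConfig:
    """Validated configuration for the simulate / validate / recommend stages."""

    cohort_path: Optional[str] = None
    generator: GeneratorParams = field(default_factory=GeneratorParams)
    grid: list[Hyperparams] = field(default_factory=lambda: list(COMPACT_GRID))
    k_outer: int = 5
    k_inner: int = 3
    tau: float = 18.0
    horizons: tuple[float, ...] = (6.0, 12.0, 18.0)
    dose_min_gy: float = 10.0
    dose_max_gy: float = 18.0
    dose_step_gy: float = 0.5
    utility: str = "lc_at_12m"
    tie_tol: float = 0.005
    bootstrap_B: int = 50
    permutation_repeats: int = 10
    seed: int = 0
    output_dir: str = "gksurv_out"

    def validate(self) -> None:
        self.generator.validate()
        if self.k_outer < 2 or self.k_inner < 2:
            raise ValueError("k_outer and k_inner must be at least 2")
        if self.tau <= 0:
            raise ValueError("tau must be positive")
        if self.dose_min_gy > self.dose_max_gy or self.dose_step_gy <= 0:
            raise ValueError("invalid dose grid bounds/step")
        if self.utility not in ("lc_at_12m", "expected_lc"):
            raise ValueError(f"unknown utility {self.utility!r}")
        if self.tie_tol < 0:
            raise ValueError("tie_tol must be non-negative")
        if not self.grid:
            raise ValueError("hyperparameter grid must be non-empty")

    def as_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["generator"] = dataclasses.asdict(self.generator)
        d["grid"] = [dataclasses.asdict(h) for h in self.grid]
        d["horizons"] = list(self.horizons)
        return d

    def dump(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.as_dict(), indent=2) + "\n")


def _parse_grid(raw: Any) -> list[Hyperparams]:
    if raw is None or raw == "compact":
        return list(COMPACT_GRID)
    if raw == "full":
        return list(DEFAULT_TUNING_GRID)
    return [Hyperparams(**{k: v for k, v in entry.items()}) for entry in raw]


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    text = Path(path).read_text()
    raw = yaml.safe_load(text) or {}
    gen_raw = raw.pop("generator", {}) or {}
    gen = GeneratorParams(**gen_raw)
    grid = _parse_grid(raw.pop("hyperparameter_grid", raw.pop("grid", None)))
    horizons = tuple(raw.pop("horizons", (6.0, 12.0, 18.0)))
    known = {f.name for f in dataclasses.fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ValueError(f"unknown config key(s): {sorted(unknown)}")
    cfg = RunConfig(generator=gen, grid=grid, horizons=horizons, **raw)
    cfg.validate()
    return cfg
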