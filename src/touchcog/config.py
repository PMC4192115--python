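"""Pipeline configuration: one YAML file driving simulate/score/compare.

The schema is strict — unknown keys anywhere in the file are rejected,
so typos cannot silently fall back to defaults.

```yaml
seed: 7
log_level: INFO
paths:
  outdir: runs/demo
cohort:
  n_young: 20
  n_aged: 10
  p_stim_bias: 0.2
  session_cap_per_phase: 100
scoring:
  accuracy_criterion: 0.80
  criterion_window: 2
  bias_alpha: 0.05
stats:
  exact_bound: 400
```
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path

import yaml

from .cohort import CohortSpec
from .scoring import ScoringConfig
from .stats import DEFAULT_EXACT_BOUND

__all__ = ["PipelineConfig", "ConfigError", "load_pipeline_config"]


class ConfigError(ValueError):
    """A pipeline configuration file violates the schema."""


@dataclass(frozen=True)
class StatsConfig:
    exact_bound: int = DEFAULT_EXACT_BOUND
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.exact_bound < 0 or not 0 < self.alpha < 1:
            raise ConfigError("invalid stats configuration")


@dataclass(frozen=True)
class PathsConfig:
    indir: str | None = None
    outdir: str | None = None


@dataclass(frozen=True)
class PipelineConfig:
    seed: int = 0
    log_level: str = "INFO"
    scoring: ScoringConfig = ScoringConfig()
    cohort: CohortSpec = CohortSpec()
    stats: StatsConfig = StatsConfig()
    paths: PathsConfig = PathsConfig()


def _build(cls, section: dict, where: str):
    if not isinstance(section, dict):
        raise ConfigError(f"{where}: expected a mapping")
    allowed = {f.name for f in fields(cls)}
    unknown = set(section) - allowed
    if unknown:
        raise ConfigError(f"{where}: unknown keys {sorted(unknown)}")
    try:
        return cls(**section)
    except (TypeError, ValueError) as e:
        raise ConfigError(f"{where}: {e}") from e


def load_pipeline_config(path: str | Path) -> PipelineConfig:
    """Load and schema-validate a pipeline configuration YAML file."""
    with open(path, encoding="utf-8") as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ConfigError("top level: expected a mapping")
    allowed = {"seed", "log_level", "scoring", "cohort", "stats", "paths"}
    unknown = set(raw) - allowed
    if unknown:
        raise ConfigError(f"top level: unknown keys {sorted(unknown)}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int):
        raise ConfigError("seed: expected an integer")
    cohort_section = dict(raw.get("cohort", {}))
    cohort_section.setdefault("seed", seed)
    return PipelineConfig(
        seed=seed,
        log_level=str(raw.get("log_level", "INFO")),
        scoring=_build(ScoringConfig, raw.get("scoring", {}), "scoring"),
        cohort=_build(CohortSpec, cohort_section, "cohort"),
        stats=_build(StatsConfig, raw.get("stats", {}), "stats"),
        paths=_build(PathsConfig, raw.get("paths", {}), "paths"),
    )
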