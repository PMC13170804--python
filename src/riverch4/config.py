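"""Pipeline configuration: validation, serialization and hashing."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import yaml

from riverch4.errors import ConfigError
from riverch4.ensemble import DEFAULT_KEEP_LIST, DEFAULT_LOG_PREDICTORS
from riverch4.synth import ALL_PREDICTORS


@dataclass
class PipelineConfig:
    """Everything the end-to-end pipeline needs, serializable to YAML."""

    out_dir: str = "artifacts"
    seed: int = 0

    # synthetic-mode sizes (ignored when explicit table paths are given)
    n_sites: int = 400
    n_cells: int = 10
    reaches_per_cell: int = 6
    truth: dict = field(default_factory=dict)  # TruthParams overrides

    # optional pre-existing input tables
    observations_path: str | None = None
    reaches_path: str | None = None
    cells_path: str | None = None

    # modelling
    predictors: Sequence[str] = ALL_PREDICTORS
    log_predictors: Sequence[str] = DEFAULT_LOG_PREDICTORS
    responses: Sequence[str] = ("ln_flux",)
    correlation_threshold: float = 0.1
    keep_list: Sequence[str] = DEFAULT_KEEP_LIST
    min_window_n: int = 5
    test_fraction: float = 0.3
    learner_params: Mapping[str, Mapping] = field(default_factory=dict)
    tuning_grids: Mapping[str, Mapping] | None = None
    tune_folds: int = 10

    # screening
    subgroup_min_n: int = 10
    loess_span: float = 0.75
    groupings: Sequence[str] = ("impacted_vs_pristine", "disturbance_type")
    density_thresholds: Sequence[float] = (0.0, 20.0, 100.0, 500.0)

    # upscaling
    ebullition_density_edges: Sequence[float] = (20.0, 200.0)
    ebullition_ratios: Sequence[float] = (0.15, 0.40, 0.80)
    extrapolate_orders: Sequence[int] = (1,)
    leap_year: bool = False

    # scenarios: list of ScenarioSpec-style dicts
    scenarios: Sequence[Mapping] = (
        {"kind": "half"},
        {"kind": "sustainable", "default_ratio": 0.3},
        {"kind": "pristine"},
    )

    def validate(self) -> None:
        if not isinstance(self.seed, int):
            raise ConfigError("seed must be an integer")
        for attr in ("n_sites", "n_cells", "reaches_per_cell"):
            if getattr(self, attr) < 1:
                raise ConfigError(f"{attr} must be >= 1")
        for attr in ("observations_path", "reaches_path", "cells_path"):
            path = getattr(self, attr)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"{attr} does not exist: {path}")
        for response in self.responses:
            if response not in ("ln_flux", "ln_conc"):
                raise ConfigError(f"unknown response {response!r}")
        if len(self.ebullition_ratios) != len(self.ebullition_density_edges) + 1:
            raise ConfigError("need len(edges) + 1 ebullition ratios")

    # -- serialization -----------------------------------------------------

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        for key, value in d.items():
            if isinstance(value, tuple):
                d[key] = list(value)
        d["scenarios"] = [dict(s) for s in self.scenarios]
        d["learner_params"] = {k: dict(v) for k, v in self.learner_params.items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "PipelineConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown config keys: {sorted(unknown)}")
        return cls(**dict(d))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls.from_dict(data)

    def to_yaml(self, path: str | Path) -> Path:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
        return path

    def config_hash(self) -> str:
        """Hash of the scientific configuration (output location excluded)."""
        d = self.to_dict()
        d.pop("out_dir", None)
        canonical = json.dumps(d, sort_keys=True, default=str)
        return hashlib.sha256(canonical.encode()).hexdigest()[:16]
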