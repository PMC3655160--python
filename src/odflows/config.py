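"""Pipeline configuration: defaults, YAML loading, validation, hashing."""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import yaml


@dataclass
class PipelineConfig:
    """All knobs for a reproducible simulate->fit->predict run."""

    workdir: str = "."
    airports_csv: str = "airports.csv"
    edges_csv: str = "edges.csv"
    flows_csv: str = "flows.csv"
    routes_csv: str = "routes.csv"
    design_csv: str = "design.csv"
    model_json: str = "model.json"
    evaluation_json: str = "evaluation.json"
    comparison_csv: str = "model_comparison.csv"
    predictions_csv: str = "flows_predicted.csv"
    summary_json: str = "summary.json"

    model: str = "lognormal_mixed"
    interactions: list = field(default_factory=lambda: [
        ["stops", "inv_distance"], ["haul_type", "inv_distance"],
        ["stops", "same_country"]])
    k_folds: int = 10
    seed: int = 0

    n_airports: int = 300
    mean_degree: float = 8.0
    n_flows: int = 5000
    sample_fraction: float = 1.0

    min_km: float = 200.0
    one_stop_cap: float = 140_086
    two_stop_cap: float = 8_060
    population_floor: float = 100_000

    mean_correction: bool = False
    directed_metrics: bool = True
    ratio_method: str = "ratio_of_logs"

    def __post_init__(self):
        for name in ("min_km", "one_stop_cap", "two_stop_cap", "population_floor"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")

    def path(self, name: str) -> Path:
        return Path(self.workdir) / getattr(self, name)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        """Stable hash of the configuration, embedded in every artifact."""
        blob = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def load_config(path=None, **overrides) -> PipelineConfig:
    """Load a YAML config file (optional) and apply CLI overrides."""
    data = {}
    if path is not None:
        data = yaml.safe_load(Path(path).read_text()) or {}
        if not isinstance(data, dict):
            raise ValueError("config file must contain a mapping")
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = set(PipelineConfig.__dataclass_fields__)
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return PipelineConfig(**data)
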