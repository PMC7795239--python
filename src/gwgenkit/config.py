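"""Run configuration: every tunable of the pipeline with its default.

The configuration round-trips through YAML or JSON unchanged, and every
stochastic stage receives an explicit seed so a run is reproducible from
its logged configuration alone.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import yaml

from .dti.config import DTIModelConfig


@dataclass
class RunConfig:
    """Paths, thresholds and seeds for a full pipeline run."""

    # inputs (disease and control edge tables may be the same candidate set)
    edges_disease: str | None = None
    edges_control: str | None = None
    expression: str | None = None
    groups: str | None = None
    gene_sets: str | None = None
    drug_tables_dir: str | None = None

    # principal network projection
    energy_threshold: float = 0.85
    top_k: int = 3000

    # comparison
    min_abs_log2fc: float = 0.5

    # drug selection
    desired_regulation: dict[str, str] = field(
        default_factory=lambda: {
            "IKK": "down",
            "STAT3": "up",
            "PPARg": "up",
            "ETS1": "down",
            "FAS": "down",
        }
    )
    max_combination_size: int = 2
    allow_unwanted: bool = True

    # DTI model
    dti: DTIModelConfig = field(default_factory=DTIModelConfig)

    # seeds
    seed: int = 0

    out_dir: str = "results"

    def __post_init__(self) -> None:
        if isinstance(self.dti, dict):
            self.dti = DTIModelConfig(**self.dti)
        if not 0 < self.energy_threshold <= 1:
            raise ValueError("energy_threshold must be in (0, 1]")
        if self.top_k < 1:
            raise ValueError("top_k must be >= 1")

    def to_dict(self) -> dict:
        d = asdict(self)
        d["dti"]["hidden_sizes"] = list(self.dti.hidden_sizes)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "dti" in d and isinstance(d["dti"], dict):
            dti = dict(d["dti"])
            if "hidden_sizes" in dti:
                dti["hidden_sizes"] = tuple(dti["hidden_sizes"])
            d["dti"] = DTIModelConfig(**dti)
        return cls(**d)

    def save(self, path: str | Path) -> None:
        path = Path(path)
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(self.to_dict(), sort_keys=False))
        else:
            path.write_text(json.dumps(self.to_dict(), indent=2) + "\n")

    @classmethod
    def load(cls, path: str | Path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        data = (
            yaml.safe_load(text)
            if path.suffix in (".yaml", ".yml")
            else json.loads(text)
        )
        return cls.from_dict(data)
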