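"""Run configuration: every pipeline default in one serializable place."""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import yaml

from .models import ModelConfig


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline parameters.

    Defaults: 8 folds of 40/10/8 balanced cohorts, top-99 ranking per fold,
    0.75 singleton screen threshold, forward selection to 12 features with a
    25-parent beam and 200 candidates per size, odd ensembles up to 101 with a
    29-member steady-state floor, and 200 validation reallocations.
    """

    matrix_path: str = ""
    labels_path: str = ""
    annotation_path: str | None = None
    out_dir: str = "run"
    orientation: str = "features_in_rows"

    n_folds: int = 8
    cohort_sizes: tuple = (40, 10, 8)
    rank_k: int = 99
    screen_threshold: float = 0.75
    screen_max_candidates: int | None = None  # None = screen the whole aggregate
    sfs_max_size: int = 12
    sfs_beam: float = 25
    sfs_cap_per_size: int = 200
    ensemble_max_size: int = 101
    ensemble_convergence_size: int = 29
    n_repeats: int = 200
    signature_score_levels: int = 2
    seed: int = 0
    model: ModelConfig = field(default_factory=ModelConfig)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["cohort_sizes"] = list(self.cohort_sizes)
        d["model"]["mlp_hidden"] = list(self.model.mlp_hidden)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        model = d.pop("model", {})
        if isinstance(model, dict):
            if "mlp_hidden" in model:
                model["mlp_hidden"] = tuple(model["mlp_hidden"])
            model = ModelConfig(**model)
        if "cohort_sizes" in d:
            d["cohort_sizes"] = tuple(d["cohort_sizes"])
        return cls(model=model, **d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]
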