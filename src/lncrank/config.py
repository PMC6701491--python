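"""Run configuration: classifier hyperparameters and pipeline knobs.

The booster defaults are the published tuning result for this framework
(546 trees of depth 10, learning rate 0.01, column subsampling 0.7, row
subsampling 0.826, gamma 0.036, binary logistic objective).  Everything
else — SMOTE neighbour count and target ratio, affinity-graph k, gap
ranks per feature category, fold count, decision threshold — is exposed
here so a run is fully described by one YAML file.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Dict, Tuple

import yaml

#: feature-category names, in canonical order
CATEGORIES = ("Genomic", "Expression", "Epigenetic", "Network")

#: default column-name prefix -> category rules
DEFAULT_CATEGORY_PREFIXES: Dict[str, str] = {
    "Gen": "Genomic",
    "Exp": "Expression",
    "Epi": "Epigenetic",
    "Net": "Network",
}

#: category -> short prefix used when naming merged (synthetic) columns
CATEGORY_PREFIX = {v: k for k, v in DEFAULT_CATEGORY_PREFIXES.items()}


@dataclass
class BoosterConfig:
    """Gradient-boosted tree hyperparameters (binary logistic objective)."""

    n_estimators: int = 546
    max_depth: int = 10
    learning_rate: float = 0.01
    colsample_bytree: float = 0.7
    subsample: float = 0.826
    gamma: float = 0.036
    objective: str = "binary:logistic"
    n_jobs: int = 1  # single-threaded deterministic mode by default
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_estimators < 1:
            raise ValueError("n_estimators must be >= 1")
        if not 0 < self.learning_rate <= 1:
            raise ValueError("learning_rate must be in (0, 1]")
        for name in ("subsample", "colsample_bytree"):
            v = getattr(self, name)
            if not 0 < v <= 1:
                raise ValueError(f"{name} must be in (0, 1]")
        if self.gamma < 0:
            raise ValueError("gamma must be >= 0")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class RunConfig:
    """Full pipeline configuration."""

    booster: BoosterConfig = field(default_factory=BoosterConfig)
    smote_k: int = 5
    smote_target_ratio: float = 1.0
    smote: bool = True
    knn_k: int = 5
    #: heat-kernel bandwidth; None self-tunes to the mean squared kNN distance
    bandwidth: float | None = None
    #: per-category (r1, r2) ranks of the score gaps used for partitioning;
    #: the Epigenetic spectrum uses its 2nd and 3rd largest gaps.
    gap_ranks: Dict[str, Tuple[int, int]] = field(
        default_factory=lambda: {
            "Genomic": (1, 2),
            "Expression": (1, 2),
            "Epigenetic": (2, 3),
            "Network": (1, 2),
        }
    )
    n_folds: int = 10
    decision_threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if isinstance(self.booster, dict):
            self.booster = BoosterConfig(**self.booster)
        for name in ("smote_k", "knn_k", "n_folds"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        if not 0 < self.smote_target_ratio <= 1:
            raise ValueError("smote_target_ratio must be in (0, 1]")
        if not 0 < self.decision_threshold < 1:
            raise ValueError("decision_threshold must be in (0, 1)")
        self.gap_ranks = {k: tuple(v) for k, v in self.gap_ranks.items()}

    def to_dict(self) -> dict:
        d = asdict(self)
        d["gap_ranks"] = {k: list(v) for k, v in self.gap_ranks.items()}
        return d


def load_config(path: str | Path | None) -> RunConfig:
    """Load a :class:`RunConfig` from YAML; ``None`` gives the defaults."""
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    return RunConfig(**raw)


def save_config(config: RunConfig, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)
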