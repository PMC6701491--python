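"""Gradient-boosted tree classifier wrapper.

Boosting internals (second-order objective, greedy split search) are
delegated to xgboost; this module pins the binary logistic objective,
applies the tuned hyperparameters, enforces a named-and-ordered feature
contract at prediction time, and exposes split-count ("weight") feature
importances.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Sequence

import json
import numpy as np
import xgboost as xgb

from .config import BoosterConfig


@dataclass
class TrainedModel:
    booster: xgb.XGBClassifier
    feature_names: List[str]
    config: BoosterConfig
    importances: Dict[str, float] = field(default_factory=dict)

    def importance_table(self) -> List[tuple]:
        """(feature, weight) pairs sorted by descending importance."""
        return sorted(self.importances.items(), key=lambda kv: (-kv[1], kv[0]))


def train_classifier(
    X: np.ndarray,
    y: np.ndarray,
    config: BoosterConfig | None = None,
    feature_names: Sequence[str] | None = None,
) -> TrainedModel:
    """Fit the boosted ensemble; reproducible given seed and n_jobs=1."""
    config = config or BoosterConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if np.isnan(X).any():
        raise ValueError("training matrix contains NaN")
    classes = np.unique(y)
    if len(classes) != 2:
        raise ValueError("binary training requires exactly two classes in y")
    if min((y == c).sum() for c in classes) < 2:
        raise ValueError("each class needs at least 2 samples")
    if feature_names is None:
        feature_names = [f"f{i}" for i in range(X.shape[1])]
    if len(feature_names) != X.shape[1]:
        raise ValueError("feature name count does not match matrix columns")

    clf = xgb.XGBClassifier(
        n_estimators=config.n_estimators,
        max_depth=config.max_depth,
        learning_rate=config.learning_rate,
        colsample_bytree=config.colsample_bytree,
        subsample=config.subsample,
        gamma=config.gamma,
        objective=config.objective,
        n_jobs=config.n_jobs,
        random_state=config.seed,
        tree_method="hist",
        importance_type="weight",
    )
    y01 = (y == classes.max()).astype(int)
    clf.fit(X, y01)

    booster = clf.get_booster()
    raw = booster.get_score(importance_type="weight")
    importances = {name: 0.0 for name in feature_names}
    for key, v in raw.items():
        # xgboost keys are f<idx> when no names were attached
        idx = int(key[1:]) if key.startswith("f") and key[1:].isdigit() else None
        name = feature_names[idx] if idx is not None else key
        importances[name] = float(v)
    return TrainedModel(clf, list(feature_names), config, importances)


def predict_scores(
    model: TrainedModel,
    X: np.ndarray,
    feature_names: Sequence[str] | None = None,
) -> np.ndarray:
    """Positive-class probability per sample.

    When ``feature_names`` is given, columns are matched by name and
    reordered to the training order; missing or unseen names are a hard
    error listing the difference.
    """
    X = np.asarray(X, dtype=float)
    if X.shape[0] == 0:
        return np.empty(0)
    if feature_names is not None:
        missing = set(model.feature_names) - set(feature_names)
        extra = set(feature_names) - set(model.feature_names)
        if missing or extra:
            raise ValueError(
                f"feature mismatch: missing {sorted(missing)}, unseen {sorted(extra)}"
            )
        order = [list(feature_names).index(n) for n in model.feature_names]
        X = X[:, order]
    elif X.shape[1] != len(model.feature_names):
        raise ValueError(
            f"matrix has {X.shape[1]} columns, model expects"
            f" {len(model.feature_names)}"
        )
    return model.booster.predict_proba(X)[:, 1]


def save_model(model: TrainedModel, path: str | Path) -> None:
    """Native booster dump plus a JSON sidecar with the feature contract."""
    path = Path(path)
    model.booster.get_booster().save_model(str(path))
    sidecar = {
        "feature_names": model.feature_names,
        "config": model.config.to_dict(),
        "importances": model.importances,
    }
    with open(path.with_suffix(path.suffix + ".meta.json"), "w") as fh:
        json.dump(sidecar, fh, indent=1)
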