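"""Rank unlabelled lncRNAs by predicted cancer-association probability."""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Set

import numpy as np

from .classifier import TrainedModel, predict_scores
from .data_io import FeatureTable


@dataclass
class PredictionRecord:
    gene_id: str
    probability: float
    rank: int
    candidate: bool


def rank_candidates(
    model: TrainedModel,
    unknown: FeatureTable,
    threshold: float = 0.5,
    training_ids: Optional[Set[str]] = None,
) -> List[PredictionRecord]:
    """Score, sort and flag candidates among unlabelled genes.

    Records are sorted by probability descending with ties broken by
    gene id, ranks run 1..n, and ``candidate`` is probability strictly
    above the threshold.  Genes seen in training are a hard error.
    """
    if training_ids:
        overlap = set(unknown.gene_ids) & set(training_ids)
        if overlap:
            raise ValueError(
                f"{len(overlap)} unknown genes overlap the training set,"
                f" e.g. {sorted(overlap)[:5]}"
            )
    probs = predict_scores(model, unknown.values, unknown.feature_names)
    order = sorted(range(len(probs)),
                   key=lambda i: (-probs[i], unknown.gene_ids[i]))
    return [
        PredictionRecord(
            gene_id=unknown.gene_ids[i],
            probability=float(probs[i]),
            rank=r + 1,
            candidate=bool(probs[i] > threshold),
        )
        for r, i in enumerate(order)
    ]


def top_n(records: Sequence[PredictionRecord], n: int) -> List[PredictionRecord]:
    return list(records[:n])
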