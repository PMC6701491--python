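"""Synthetic Minority Over-sampling Technique (SMOTE).

New minority samples are linear interpolations x + u (x_nn - x) between
a minority point x and one of its k nearest minority neighbours x_nn,
with u ~ Uniform(0, 1).  Enough synthetic rows are generated to bring
the minority/majority ratio up to ``target_ratio``; majority rows are
never touched.  This is the resampler applied inside cross-validation
to training folds only — validation folds are never resampled.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from sklearn.neighbors import NearestNeighbors

logger = logging.getLogger(__name__)


@dataclass
class ResampledSet:
    values: np.ndarray        # original rows first, synthetic rows appended
    labels: np.ndarray
    synthetic_mask: np.ndarray  # True = generated row


def n_synthetic_needed(n_minority: int, n_majority: int, target_ratio: float) -> int:
    """ceil(target_ratio * |majority|) - |minority|, floored at zero."""
    return max(0, math.ceil(target_ratio * n_majority) - n_minority)


def smote_oversample(
    X: np.ndarray,
    y: np.ndarray,
    k: int = 5,
    target_ratio: float = 1.0,
    rng_seed: int | np.random.Generator = 0,
) -> ResampledSet:
    """Over-sample the minority class of a binary problem.

    Parameters
    ----------
    X, y
        Sample matrix and binary label vector (any two label values).
    k
        Minority nearest-neighbour count; clamped to |minority| - 1 with
        a warning when the minority class is smaller than k + 1.
    target_ratio
        Desired |minority| / |majority| after augmentation, in (0, 1].
    rng_seed
        Integer seed or a ready generator; drives both the seed-point
        and neighbour choices and the interpolation coefficients.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    if X.shape[0] != y.shape[0]:
        raise ValueError("X and y length mismatch")
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError(f"need exactly two classes, got {list(classes)}")
    if not 0 < target_ratio <= 1:
        raise ValueError("target_ratio must be in (0, 1]")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()

    n_new = n_synthetic_needed(int(n_min), int(n_maj), target_ratio)
    empty = np.zeros(len(y), dtype=bool)
    if n_new == 0:
        return ResampledSet(X.copy(), y.copy(), empty)

    if n_min < 2:
        raise ValueError("minority class needs at least 2 samples for SMOTE")
    if k > n_min - 1:
        logger.warning("k = %d clamped to %d (minority size %d)", k, n_min - 1, n_min)
        k = int(n_min - 1)

    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    Xmin = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k + 1).fit(Xmin)
    _, neigh = nn.kneighbors(Xmin)  # column 0 is the point itself (or a twin)
    neigh = np.array([
        [j for j in row if j != i][:k] for i, row in enumerate(neigh)
    ])

    seeds = rng.integers(0, len(Xmin), size=n_new)
    picks = rng.integers(0, k, size=n_new)
    u = rng.uniform(0.0, 1.0, size=n_new)
    base = Xmin[seeds]
    partner = Xmin[neigh[seeds, picks]]
    synth = base + u[:, None] * (partner - base)

    values = np.vstack([X, synth])
    labels = np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)])
    mask = np.concatenate([empty, np.ones(n_new, dtype=bool)])
    return ResampledSet(values, labels, mask)
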