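"""Unsupervised feature selection by Laplacian score with gap partitioning.

A kNN affinity graph is built over the samples (Euclidean metric on
standardized columns, heat-kernel weights).  Each feature f is scored by
the Rayleigh quotient of the graph Laplacian,

    score(f) = f~' L f~ / f~' D f~,   f~ = f - (f' D 1 / 1' D 1) 1,

where small scores mean the feature varies smoothly along the sample
manifold, i.e. is more informative in the locality-preserving sense.
Within each feature category the sorted score spectrum is cut at its two
largest gaps (rank-configurable) into lower / middle / upper parts; the
lower part is kept verbatim and the middle and upper parts are each
replaced by their per-sample mean — a single "synthetic" feature named
``<Prefix>_LevelOne`` / ``<Prefix>_LevelTwo``.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
from scipy.sparse import csr_matrix
from sklearn.neighbors import NearestNeighbors

from .config import CATEGORY_PREFIX, RunConfig
from .data_io import FeatureMeta, FeatureTable

logger = logging.getLogger(__name__)

#: score assigned to constant (zero-variance) features
CONSTANT_SENTINEL = np.inf


# ---------------------------------------------------------------------------
# affinity graph
# ---------------------------------------------------------------------------

@dataclass
class AffinityGraph:
    W: csr_matrix          # symmetric non-negative weights, zero diagonal
    degrees: np.ndarray    # D_ii = sum_j W_ij
    k: int
    bandwidth: float

    @property
    def n(self) -> int:
        return self.W.shape[0]


def standardize(values: np.ndarray) -> np.ndarray:
    """Center each column and scale to unit variance (constant cols -> 0)."""
    mu = values.mean(axis=0)
    sd = values.std(axis=0)
    sd[sd == 0] = 1.0
    return (values - mu) / sd


def build_affinity_graph(
    table: FeatureTable,
    k: int = 5,
    bandwidth: float | None = None,
    mutual: bool = False,
    pre_standardized: bool = False,
) -> AffinityGraph:
    """kNN graph with heat-kernel weights exp(-d^2 / t).

    ``bandwidth=None`` (the default) self-tunes t to the mean squared
    kNN distance, which keeps weights in a usable range regardless of
    the dimensionality; a fixed t underflows to an empty graph once
    typical squared distances exceed a few hundred.  Edges are
    symmetrized by union (``mutual=False``) or by intersection.
    Columns are standardized first unless the caller already did.
    """
    X = table.values if pre_standardized else standardize(table.values)
    n = X.shape[0]
    if k >= n:
        raise ValueError(f"k = {k} must be smaller than the sample count {n}")
    if bandwidth is not None and bandwidth <= 0:
        raise ValueError("bandwidth must be positive")

    nn = NearestNeighbors(n_neighbors=k + 1, metric="euclidean").fit(X)
    dist, idx = nn.kneighbors(X)
    # drop each point itself; with duplicate rows the self column may not
    # be first, so mask one zero-distance occurrence of the own index
    rows, cols, d2 = [], [], []
    for i in range(n):
        neigh = [(idx[i, j], dist[i, j]) for j in range(k + 1)]
        if i in idx[i]:
            pos = list(idx[i]).index(i)
            neigh.pop(pos)
        else:
            neigh.pop(-1)
        for j, dij in neigh[:k]:
            rows.append(i)
            cols.append(j)
            d2.append(dij * dij)
    d2 = np.asarray(d2)
    if bandwidth is None:
        bandwidth = float(d2.mean()) or 1.0
    w = np.exp(-d2 / bandwidth)
    A = csr_matrix((w, (rows, cols)), shape=(n, n))
    if mutual:
        W = A.minimum(A.T)
    else:
        W = A.maximum(A.T)
    W.setdiag(0)
    W.eliminate_zeros()
    degrees = np.asarray(W.sum(axis=1)).ravel()
    n_iso = int((degrees == 0).sum())
    if n_iso:
        logger.warning("%d isolated samples in the affinity graph", n_iso)
    return AffinityGraph(W=W, degrees=degrees, k=k, bandwidth=bandwidth)


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

@dataclass
class FeatureScore:
    name: str
    category: str
    score: float


def laplacian_scores(
    table: FeatureTable,
    graph: AffinityGraph,
    pre_standardized: bool = False,
) -> List[FeatureScore]:
    """Laplacian score per feature; smaller = more important.

    Constant features have a zero-variance denominator and receive the
    +inf sentinel, which parks them in the least-important (upper) part.
    """
    X = table.values if pre_standardized else standardize(table.values)
    if X.shape[0] != graph.n:
        raise ValueError("graph was built on a different number of samples")
    d = graph.degrees
    dsum = d.sum()
    scores = []
    WX = graph.W @ X  # (n, p)
    for r, meta in enumerate(table.features):
        f = X[:, r]
        ftilde = f - (f @ d) / dsum
        denom = (ftilde * ftilde) @ d
        if denom <= 1e-12:
            logger.warning("feature %s is constant; sentinel score", meta.name)
            scores.append(FeatureScore(meta.name, meta.category, CONSTANT_SENTINEL))
            continue
        # f~' L f~ = f~' D f~ - f~' W f~ ; W (f - c 1) = W f - c d
        shift = (f @ d) / dsum
        wf = WX[:, r] - shift * d
        numer = denom - ftilde @ wf
        scores.append(FeatureScore(meta.name, meta.category, float(numer / denom)))
    return scores


# ---------------------------------------------------------------------------
# gap partitioning
# ---------------------------------------------------------------------------

@dataclass
class CategoryPartition:
    category: str
    lower: List[str]
    middle: List[str]
    upper: List[str]
    thresholds: List[Tuple[int, float]]  # (gap position, gap magnitude)
    gap_ranks: Tuple[int, int]

    @property
    def all_features(self) -> List[str]:
        return self.lower + self.middle + self.upper


def partition_by_gaps(
    scores: Sequence[FeatureScore],
    gap_ranks: Tuple[int, int] = (1, 2),
) -> CategoryPartition:
    """Split one category's features at the gap_ranks-th largest score gaps.

    Scores are sorted ascending; consecutive differences are ranked by
    magnitude (descending, ties broken toward the earlier position) and
    the two chosen gaps bound lower|middle and middle|upper.  Sentinel
    (constant-feature) scores bypass the gap logic and land in upper.
    Categories with fewer than 4 finite-scored features are not split.
    """
    if not scores:
        raise ValueError("cannot partition an empty score list")
    category = scores[0].category
    r1, r2 = gap_ranks
    if not (1 <= r1 < r2):
        raise ValueError("gap ranks must satisfy 1 <= r1 < r2")

    finite = [s for s in scores if np.isfinite(s.score)]
    sentinel_upper = [s.name for s in scores if not np.isfinite(s.score)]
    order = sorted(finite, key=lambda s: (s.score, s.name))
    names = [s.name for s in order]
    vals = np.array([s.score for s in order])

    if len(order) < 4 or r2 > len(order) - 1:
        if len(order) < 4:
            logger.warning(
                "category %s has %d scoreable features; no split",
                category, len(order),
            )
        else:
            logger.warning(
                "category %s has too few gaps for ranks %s; no split",
                category, gap_ranks,
            )
        return CategoryPartition(category, names, [], sentinel_upper, [], gap_ranks)

    gaps = np.diff(vals)  # gaps[i] sits between positions i and i+1
    # rank gaps by magnitude desc; ties toward the earlier position
    rank_order = sorted(range(len(gaps)), key=lambda i: (-gaps[i], i))
    chosen = sorted([rank_order[r1 - 1], rank_order[r2 - 1]])
    cut1, cut2 = chosen
    lower = names[: cut1 + 1]
    middle = names[cut1 + 1: cut2 + 1]
    upper = names[cut2 + 1:] + sentinel_upper
    thresholds = [(int(c), float(gaps[c])) for c in chosen]
    return CategoryPartition(category, lower, middle, upper, thresholds, gap_ranks)


def partition_all_categories(
    scores: Sequence[FeatureScore],
    gap_ranks: Optional[Dict[str, Tuple[int, int]]] = None,
) -> Dict[str, CategoryPartition]:
    """Partition every category present in ``scores``."""
    gap_ranks = gap_ranks or {}
    out = {}
    categories = []
    for s in scores:
        if s.category not in categories:
            categories.append(s.category)
    for cat in categories:
        ranks = tuple(gap_ranks.get(cat, (1, 2)))
        out[cat] = partition_by_gaps(
            [s for s in scores if s.category == cat], ranks
        )
    return out


# ---------------------------------------------------------------------------
# mean-merge
# ---------------------------------------------------------------------------

def merge_partition(
    table: FeatureTable, partitions: Dict[str, CategoryPartition]
) -> FeatureTable:
    """Build the reduced table: lower parts verbatim, middle/upper merged.

    Per category the middle part becomes ``<Prefix>_LevelOne`` and the
    upper part ``<Prefix>_LevelTwo`` (row-wise means, flagged synthetic);
    an empty part emits no column.
    """
    col_of = {f.name: i for i, f in enumerate(table.features)}
    assigned = [n for p in partitions.values() for n in p.all_features]
    unknown = set(assigned) - set(col_of)
    if unknown:
        raise ValueError(f"partition references unknown features: {sorted(unknown)[:5]}")
    if sorted(assigned) != sorted(col_of):
        raise ValueError("every table feature must appear in exactly one part")

    columns: List[np.ndarray] = []
    metas: List[FeatureMeta] = []
    for cat, part in partitions.items():
        prefix = CATEGORY_PREFIX.get(cat, cat[:3])
        keep_idx = sorted(col_of[n] for n in part.lower)
        for i in keep_idx:
            columns.append(table.values[:, i])
            metas.append(FeatureMeta(table.features[i].name, cat, synthetic=False))
        for part_names, level in ((part.middle, "LevelOne"), (part.upper, "LevelTwo")):
            if not part_names:
                continue
            idx = [col_of[n] for n in part_names]
            columns.append(table.values[:, idx].mean(axis=1))
            metas.append(FeatureMeta(f"{prefix}_{level}", cat, synthetic=True))
    return FeatureTable(list(table.gene_ids), np.column_stack(columns), metas)


def select_features(
    table: FeatureTable, config: Optional[RunConfig] = None
) -> Tuple[FeatureTable, List[FeatureScore], Dict[str, CategoryPartition]]:
    """Full selection pass: graph -> scores -> partitions -> reduced table."""
    config = config or RunConfig()
    X = standardize(table.values)
    std_table = FeatureTable(list(table.gene_ids), X, list(table.features))
    graph = build_affinity_graph(
        std_table, k=config.knn_k, bandwidth=config.bandwidth,
        pre_standardized=True,
    )
    scores = laplacian_scores(std_table, graph, pre_standardized=True)
    partitions = partition_all_categories(scores, config.gap_ranks)
    reduced = merge_partition(table, partitions)
    return reduced, scores, partitions
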