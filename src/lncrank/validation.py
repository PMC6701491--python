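"""Candidate-credibility statistics.

Given gene intervals, somatic mutation positions, and paired
tumour/normal expression, this module compares gene sets (positive,
negative, predicted, random background) on three axes the field treats
as corroborating evidence of cancer relevance:

* somatic mutation burden per gene body,
* genomic distance to the nearest cancer protein-coding gene,
* fraction of genes differentially expressed (|log2 fold change| > 1)
  between tumour and matched normal tissue,

with two-sample Kolmogorov-Smirnov tests between the per-gene
distributions.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence, Tuple

import numpy as np
from scipy.stats import distributions

from .data_io import ExpressionPairTable, GenomicInterval, MutationTable

logger = logging.getLogger(__name__)

#: sentinel distance for queries with no same-chromosome target
NO_TARGET = np.inf


# ---------------------------------------------------------------------------
# mutation burden
# ---------------------------------------------------------------------------

def mutation_counts(
    intervals: Sequence[GenomicInterval], mutations: MutationTable
) -> Dict[str, int]:
    """Somatic mutations per gene body (half-open containment).

    Overlapping genes each count a shared mutation; genes without
    mutations get 0.  Assumes intervals and mutations share an assembly.
    """
    by_chrom: Dict[str, np.ndarray] = {}
    for chrom in set(mutations.chrom.tolist()):
        sel = mutations.chrom == chrom
        by_chrom[chrom] = np.sort(mutations.pos[sel])
    counts = {}
    for iv in intervals:
        pos = by_chrom.get(iv.chrom)
        if pos is None:
            counts[iv.gene_id] = 0
            continue
        lo = np.searchsorted(pos, iv.start, side="left")
        hi = np.searchsorted(pos, iv.end, side="left")  # end exclusive
        counts[iv.gene_id] = int(hi - lo)
    return counts


# ---------------------------------------------------------------------------
# nearest-gene distance
# ---------------------------------------------------------------------------

def nearest_distance(
    query: Sequence[GenomicInterval], targets: Sequence[GenomicInterval]
) -> Dict[str, float]:
    """Gap to the closest same-chromosome target per query gene.

    0 for overlapping or abutting intervals (half-open convention);
    queries with no same-chromosome target get the +inf sentinel and
    are excluded from downstream KS tests (count logged by the caller).
    """
    if not targets:
        raise ValueError("target interval list must be non-empty")
    starts: Dict[str, np.ndarray] = {}
    ends: Dict[str, np.ndarray] = {}
    for chrom in {t.chrom for t in targets}:
        tc = [t for t in targets if t.chrom == chrom]
        starts[chrom] = np.array([t.start for t in tc])
        ends[chrom] = np.array([t.end for t in tc])
    out = {}
    for q in query:
        if q.chrom not in starts:
            out[q.gene_id] = NO_TARGET
            continue
        s, e = starts[q.chrom], ends[q.chrom]
        # gap is 0 when intervals overlap/abut, else the separation
        gap = np.maximum.reduce([s - q.end, q.start - e, np.zeros(len(s))])
        out[q.gene_id] = float(gap.min())
    return out


def random_background_positions(
    chrom_sizes: Dict[str, int], n: int, rng_seed: int | np.random.Generator = 0
) -> List[GenomicInterval]:
    """n width-1 points, chromosome chosen proportional to its length."""
    if n <= 0:
        raise ValueError("n must be positive")
    if not chrom_sizes or min(chrom_sizes.values()) <= 0:
        raise ValueError("chromosome sizes must be positive")
    rng = (rng_seed if isinstance(rng_seed, np.random.Generator)
           else np.random.default_rng(rng_seed))
    chroms = list(chrom_sizes)
    sizes = np.array([chrom_sizes[c] for c in chroms], dtype=float)
    picks = rng.choice(len(chroms), size=n, p=sizes / sizes.sum())
    out = []
    for i, ci in enumerate(picks):
        pos = int(rng.integers(0, chrom_sizes[chroms[ci]]))
        out.append(GenomicInterval(chroms[ci], pos, pos + 1, f"bg_{i}"))
    return out


# ---------------------------------------------------------------------------
# differential expression
# ---------------------------------------------------------------------------

def de_fraction(
    expr: ExpressionPairTable,
    gene_set: Iterable[str],
    fc_threshold: float = 1.0,
    pseudocount: float = 1.0,
    mode: str = "median",
) -> float:
    """Fraction of the gene set differentially expressed.

    Per gene and tumour/normal pair, log2FC = log2((t + eps)/(n + eps));
    a gene is DE when the median |log2FC| across pairs exceeds the
    threshold (``mode="any"`` instead requires a single exceeding pair).
    """
    gene_set = set(gene_set)
    idx = [i for i, g in enumerate(expr.gene_ids) if g in gene_set]
    if not idx:
        raise ValueError("gene set shares no genes with the expression table")
    lfc = np.log2((expr.tumor[idx] + pseudocount) /
                  (expr.normal[idx] + pseudocount))
    if mode == "median":
        de = np.abs(np.median(lfc, axis=1)) > fc_threshold
    elif mode == "any":
        de = (np.abs(lfc) > fc_threshold).any(axis=1)
    else:
        raise ValueError(f"unknown DE mode {mode!r}")
    return float(de.mean())


def median_log2fc(
    expr: ExpressionPairTable, gene_set: Iterable[str], pseudocount: float = 1.0
) -> np.ndarray:
    """Per-gene median log2 fold change for the genes of the set."""
    gene_set = set(gene_set)
    idx = [i for i, g in enumerate(expr.gene_ids) if g in gene_set]
    if not idx:
        raise ValueError("gene set shares no genes with the expression table")
    lfc = np.log2((expr.tumor[idx] + pseudocount) /
                  (expr.normal[idx] + pseudocount))
    return np.median(lfc, axis=1)


# ---------------------------------------------------------------------------
# Kolmogorov-Smirnov
# ---------------------------------------------------------------------------

def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> Tuple[float, float]:
    """Two-sample KS: D = sup |ECDF_a - ECDF_b|, asymptotic p-value.

    p uses the Kolmogorov limiting distribution at effective size
    n_eff = |a| |b| / (|a| + |b|), i.e. p = Q_KS(sqrt(n_eff) * D).
    """
    a = np.sort(np.asarray(a, dtype=float))
    b = np.sort(np.asarray(b, dtype=float))
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be non-empty")
    grid = np.concatenate([a, b])
    cdf_a = np.searchsorted(a, grid, side="right") / len(a)
    cdf_b = np.searchsorted(b, grid, side="right") / len(b)
    d = float(np.abs(cdf_a - cdf_b).max())
    n_eff = len(a) * len(b) / (len(a) + len(b))
    p = float(distributions.kstwobign.sf(math.sqrt(n_eff) * d))
    return d, min(max(p, np.finfo(float).tiny), 1.0)


# ---------------------------------------------------------------------------
# report
# ---------------------------------------------------------------------------

@dataclass
class ValidationReport:
    mutation_counts: Dict[str, Dict[str, int]]      # set name -> gene -> count
    distances: Dict[str, Dict[str, float]]          # set name -> gene -> bp
    de_fractions: Dict[str, float]                  # set name -> fraction
    ks_results: Dict[str, Tuple[float, float]]      # "axis:setA|setB" -> (D, p)
    excluded: Dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "de_fractions": self.de_fractions,
            "ks_results": {k: {"D": d, "p": p}
                           for k, (d, p) in self.ks_results.items()},
            "excluded_no_target": self.excluded,
            "mutation_mean": {
                s: float(np.mean(list(c.values()))) if c else 0.0
                for s, c in self.mutation_counts.items()
            },
            "distance_median": {
                s: float(np.median([v for v in d.values() if np.isfinite(v)]))
                if d else 0.0
                for s, d in self.distances.items()
            },
        }


def build_validation_report(
    gene_sets: Dict[str, Sequence[GenomicInterval]],
    cancer_genes: Sequence[GenomicInterval],
    mutations: MutationTable,
    expr: ExpressionPairTable,
    chrom_sizes: Dict[str, int],
    n_background: int = 500,
    rng_seed: int = 0,
    ks_pairs: Sequence[Tuple[str, str]] = (),
) -> ValidationReport:
    """Run the full battery over named gene sets (intervals per set)."""
    sets = dict(gene_sets)
    sets["background"] = random_background_positions(
        chrom_sizes, n_background, rng_seed
    )
    mut = {name: mutation_counts(ivs, mutations) for name, ivs in sets.items()}
    dist = {name: nearest_distance(ivs, cancer_genes) for name, ivs in sets.items()}
    excluded = {
        name: sum(1 for v in d.values() if not np.isfinite(v))
        for name, d in dist.items()
    }
    for name, n_excl in excluded.items():
        if n_excl:
            logger.warning("%d genes in %s have no same-chromosome cancer gene",
                           n_excl, name)

    expr_ids = set(expr.gene_ids)
    de = {}
    for name, ivs in gene_sets.items():
        ids = [iv.gene_id for iv in ivs]
        if expr_ids & set(ids):
            de[name] = de_fraction(expr, ids)

    pairs = list(ks_pairs) or [
        (a, b) for i, a in enumerate(sets) for b in list(sets)[i + 1:]
    ]
    ks: Dict[str, Tuple[float, float]] = {}
    for a, b in pairs:
        ks[f"mutations:{a}|{b}"] = ks_two_sample(
            list(mut[a].values()), list(mut[b].values())
        )
        da = [v for v in dist[a].values() if np.isfinite(v)]
        db = [v for v in dist[b].values() if np.isfinite(v)]
        if da and db:
            ks[f"distance:{a}|{b}"] = ks_two_sample(da, db)
        if a in de and b in de:
            ks[f"log2fc:{a}|{b}"] = ks_two_sample(
                np.abs(median_log2fc(expr, [iv.gene_id for iv in gene_sets[a]])),
                np.abs(median_log2fc(expr, [iv.gene_id for iv in gene_sets[b]])),
            )
    return ValidationReport(mut, dist, de, ks, excluded)
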