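"""Readers and writers for every on-disk artifact the pipeline touches.

Formats are deliberately plain: a wide TSV feature table (one row per
lncRNA, one column per numeric feature, column names carrying a category
prefix such as ``Gen_``/``Exp_``/``Epi_``/``Net_``), one-ID-per-line
label lists, BED3/BED4 intervals (0-based half-open), a mutation TSV
(chrom, pos, sample_id), and a paired tumour/normal expression TSV.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Iterable, List, Optional, Sequence

import numpy as np
import pandas as pd

from .config import DEFAULT_CATEGORY_PREFIXES

logger = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class FeatureMeta:
    name: str
    category: str
    synthetic: bool = False


@dataclass
class FeatureTable:
    """Dense gene x feature matrix with per-feature category metadata."""

    gene_ids: List[str]
    values: np.ndarray  # shape (n_genes, n_features)
    features: List[FeatureMeta]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n, p = self.values.shape
        if n != len(self.gene_ids):
            raise ValueError("row count does not match number of gene ids")
        if p != len(self.features):
            raise ValueError("column count does not match feature metadata")
        if len(set(self.gene_ids)) != n:
            raise ValueError("gene ids must be unique")
        names = [f.name for f in self.features]
        if len(set(names)) != p:
            raise ValueError("feature names must be unique")
        if not np.isfinite(self.values).all():
            raise ValueError("feature values must all be finite")

    @property
    def feature_names(self) -> List[str]:
        return [f.name for f in self.features]

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    def category_columns(self, category: str) -> List[int]:
        return [i for i, f in enumerate(self.features) if f.category == category]

    def subset_genes(self, gene_ids: Sequence[str]) -> "FeatureTable":
        index = {g: i for i, g in enumerate(self.gene_ids)}
        rows = [index[g] for g in gene_ids]
        return FeatureTable(list(gene_ids), self.values[rows], list(self.features))

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, columns=self.feature_names)
        df.insert(0, "gene_id", self.gene_ids)
        return df


@dataclass
class LabelSet:
    """Disjoint positive / negative / unknown gene-ID sets."""

    positive: set
    negative: set
    unknown: set = field(default_factory=set)

    def __post_init__(self) -> None:
        if self.positive & self.negative or self.positive & self.unknown \
                or self.negative & self.unknown:
            raise ValueError("label sets must be pairwise disjoint")


@dataclass
class GenomicInterval:
    """0-based half-open interval; strand is carried but never used."""

    chrom: str
    start: int
    end: int
    gene_id: str = "."
    strand: str = "."

    def __post_init__(self) -> None:
        if not 0 <= self.start < self.end:
            raise ValueError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )


@dataclass
class MutationTable:
    """Somatic mutation records: (chrom, 0-based position, sample id)."""

    chrom: np.ndarray
    pos: np.ndarray
    sample_id: np.ndarray

    def __post_init__(self) -> None:
        self.chrom = np.asarray(self.chrom, dtype=object)
        self.pos = np.asarray(self.pos, dtype=np.int64)
        self.sample_id = np.asarray(self.sample_id, dtype=object)
        if (self.pos < 0).any():
            raise ValueError("mutation positions must be >= 0")

    def __len__(self) -> int:
        return len(self.pos)


@dataclass
class ExpressionPairTable:
    """Paired tumour/normal expression: columns <sample>_tumor / <sample>_normal."""

    gene_ids: List[str]
    tumor: np.ndarray   # (n_genes, n_pairs)
    normal: np.ndarray  # (n_genes, n_pairs)
    sample_ids: List[str]

    def __post_init__(self) -> None:
        self.tumor = np.asarray(self.tumor, dtype=float)
        self.normal = np.asarray(self.normal, dtype=float)
        if self.tumor.shape != self.normal.shape:
            raise ValueError("tumor and normal matrices must have equal shape")
        if self.tumor.shape != (len(self.gene_ids), len(self.sample_ids)):
            raise ValueError("expression matrix shape mismatch")
        if (self.tumor < 0).any() or (self.normal < 0).any():
            raise ValueError("expression values must be non-negative")


# ---------------------------------------------------------------------------
# feature table
# ---------------------------------------------------------------------------

def assign_categories(
    names: Iterable[str],
    category_map: Optional[Dict[str, str]] = None,
    sidecar: Optional[Dict[str, str]] = None,
) -> List[str]:
    """Map column names to categories by prefix rule, sidecar wins."""
    rules = category_map or DEFAULT_CATEGORY_PREFIXES
    out = []
    for name in names:
        if sidecar and name in sidecar:
            out.append(sidecar[name])
            continue
        for prefix, category in rules.items():
            if name.startswith(prefix):
                out.append(category)
                break
        else:
            raise ValueError(
                f"column {name!r} matches no category prefix "
                f"({sorted(rules)}) and no sidecar entry"
            )
    return out


def read_feature_table(
    path: str | Path,
    category_map: Optional[Dict[str, str]] = None,
    category_sidecar: Optional[str | Path] = None,
    impute_missing: bool = False,
) -> FeatureTable:
    """Read a wide TSV feature table (first column = gene ID).

    Missing cells (``NA``/empty) are a hard error unless ``impute_missing``
    replaces them with the column mean.
    """
    df = pd.read_csv(path, sep="\t", dtype={0: str}, na_values=["NA", ""],
                     keep_default_na=False)
    if df.shape[0] == 0:
        raise ValueError(f"empty table: {path}")
    if df.shape[1] < 2:
        raise ValueError(f"no feature columns in {path}")
    gene_col = df.columns[0]
    gene_ids = df[gene_col].tolist()
    if len(set(gene_ids)) != len(gene_ids):
        dupes = df[gene_col][df[gene_col].duplicated()].unique()[:5]
        raise ValueError(f"duplicate gene ids in {path}: {list(dupes)}")
    feat_names = list(df.columns[1:])
    if len(set(feat_names)) != len(feat_names):
        raise ValueError(f"duplicate feature names in {path}")

    matrix = np.empty((len(gene_ids), len(feat_names)), dtype=float)
    for j, name in enumerate(feat_names):
        col = pd.to_numeric(df[name], errors="coerce")
        bad = col.isna() & df[name].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ValueError(
                f"non-numeric cell at gene {gene_ids[row]!r}, column {name!r}"
            )
        if col.isna().any():
            if not impute_missing:
                row = int(np.flatnonzero(col.isna().to_numpy())[0])
                raise ValueError(
                    f"missing value at gene {gene_ids[row]!r}, column {name!r}"
                    " (pass impute_missing=True to mean-impute)"
                )
            col = col.fillna(col.mean())
        matrix[:, j] = col.to_numpy()

    sidecar = None
    if category_sidecar is not None:
        sc = pd.read_csv(category_sidecar, sep="\t", header=None,
                         names=["feature", "category"])
        sidecar = dict(zip(sc["feature"], sc["category"]))
    categories = assign_categories(feat_names, category_map, sidecar)
    features = [FeatureMeta(n, c) for n, c in zip(feat_names, categories)]
    return FeatureTable(gene_ids, matrix, features)


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    table.to_frame().to_csv(path, sep="\t", index=False)


def write_feature_metadata(table: FeatureTable, path: str | Path) -> None:
    """Sidecar TSV with (feature, category, synthetic) per column."""
    pd.DataFrame(
        {
            "feature": table.feature_names,
            "category": [f.category for f in table.features],
            "synthetic": [int(f.synthetic) for f in table.features],
        }
    ).to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# label sets
# ---------------------------------------------------------------------------

def _read_id_list(path: str | Path) -> List[str]:
    ids = []
    with open(path) as fh:
        for line in fh:
            token = line.strip()
            if token:
                ids.append(token)
    return ids


def read_label_sets(
    pos_path: str | Path, neg_path: str | Path, table: FeatureTable
) -> LabelSet:
    """Read positive/negative ID lists; the rest of the table is unknown.

    IDs absent from the table are dropped with a warning; an ID in both
    lists is a hard error.
    """
    pos = set(_read_id_list(pos_path))
    neg = set(_read_id_list(neg_path))
    if not pos or not neg:
        raise ValueError("positive and negative sets must be non-empty")
    both = pos & neg
    if both:
        raise ValueError(f"ids present in both label files: {sorted(both)[:5]}")
    known = set(table.gene_ids)
    dropped = (pos | neg) - known
    if dropped:
        logger.warning(
            "%d labelled ids absent from the feature table were dropped",
            len(dropped),
        )
    pos &= known
    neg &= known
    if not pos or not neg:
        raise ValueError("positive and negative sets must be non-empty")
    unknown = known - pos - neg
    return LabelSet(pos, neg, unknown)


def write_id_list(ids: Iterable[str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid in ids:
            fh.write(f"{gid}\n")


# ---------------------------------------------------------------------------
# intervals / mutations / expression
# ---------------------------------------------------------------------------

def read_intervals(path: str | Path) -> List[GenomicInterval]:
    """Read BED3+ (0-based half-open, optional name and strand columns)."""
    out = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"{path}: line {lineno}: fewer than 3 BED fields")
            chrom, start, end = parts[0], int(parts[1]), int(parts[2])
            if start >= end:
                raise ValueError(
                    f"{path}: line {lineno}: start {start} >= end {end}"
                )
            name = parts[3] if len(parts) > 3 else "."
            strand = parts[5] if len(parts) > 5 else "."
            out.append(GenomicInterval(chrom, start, end, name, strand))
    return out


def write_intervals(intervals: Sequence[GenomicInterval], path: str | Path) -> None:
    with open(path, "w") as fh:
        for iv in intervals:
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{iv.gene_id}\t0\t{iv.strand}\n")


def read_mutations(path: str | Path) -> MutationTable:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str, "sample_id": str})
    for col in ("chrom", "pos", "sample_id"):
        if col not in df.columns:
            raise ValueError(f"mutation table {path} lacks column {col!r}")
    return MutationTable(df["chrom"].to_numpy(), df["pos"].to_numpy(),
                         df["sample_id"].to_numpy())


def write_mutations(muts: MutationTable, path: str | Path) -> None:
    pd.DataFrame({"chrom": muts.chrom, "pos": muts.pos,
                  "sample_id": muts.sample_id}).to_csv(path, sep="\t", index=False)


def read_expression_pairs(path: str | Path) -> ExpressionPairTable:
    """Read a TSV with gene_id then <sample>_tumor/<sample>_normal pairs."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if "gene_id" not in df.columns:
        raise ValueError(f"expression table {path} lacks a gene_id column")
    tumor_cols = sorted(c for c in df.columns if c.endswith("_tumor"))
    normal_cols = sorted(c for c in df.columns if c.endswith("_normal"))
    t_samples = [c[: -len("_tumor")] for c in tumor_cols]
    n_samples = [c[: -len("_normal")] for c in normal_cols]
    if t_samples != n_samples or not t_samples:
        raise ValueError(
            f"expression table {path}: tumor/normal columns must come in"
            " complete <sample>_tumor/<sample>_normal pairs"
        )
    return ExpressionPairTable(
        df["gene_id"].tolist(),
        df[tumor_cols].to_numpy(float),
        df[normal_cols].to_numpy(float),
        t_samples,
    )


def write_expression_pairs(expr: ExpressionPairTable, path: str | Path) -> None:
    df = pd.DataFrame({"gene_id": expr.gene_ids})
    for j, s in enumerate(expr.sample_ids):
        df[f"{s}_tumor"] = expr.tumor[:, j]
        df[f"{s}_normal"] = expr.normal[:, j]
    df.to_csv(path, sep="\t", index=False)


def read_chrom_sizes(path: str | Path) -> Dict[str, int]:
    sizes = {}
    with open(path) as fh:
        for line in fh:
            if line.strip():
                chrom, size = line.split("\t")[:2]
                sizes[chrom] = int(size)
    return sizes


def write_chrom_sizes(sizes: Dict[str, int], path: str | Path) -> None:
    with open(path, "w") as fh:
        for chrom, size in sizes.items():
            fh.write(f"{chrom}\t{size}\n")


# ---------------------------------------------------------------------------
# predictions
# ---------------------------------------------------------------------------

def write_predictions(records, path: str | Path) -> None:
    """Write ranked predictions as TSV (gene_id, probability, rank, candidate).

    ``records`` must already be sorted by descending probability; the byte
    output is deterministic for a fixed input.
    """
    probs = [r.probability for r in records]
    if any(not np.isfinite(p) for p in probs):
        raise ValueError("prediction probabilities must be finite")
    if any(probs[i] < probs[i + 1] for i in range(len(probs) - 1)):
        raise ValueError("records must be sorted by descending probability")
    with open(path, "w") as fh:
        fh.write("gene_id\tprobability\trank\tcandidate\n")
        for r in records:
            fh.write(f"{r.gene_id}\t{r.probability:.6f}\t{r.rank}\t{int(r.candidate)}\n")


def read_predictions(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    expected = ["gene_id", "probability", "rank", "candidate"]
    if list(df.columns) != expected:
        raise ValueError(f"prediction file {path} must have columns {expected}")
    return df
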