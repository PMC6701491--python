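"""End-to-end orchestration: select features -> CV -> train -> predict.

Each stage consumes and produces files only, so a run can be resumed or
audited stage by stage; a manifest records the config echo, SHA-256
digests of every input, per-stage wall time, and every output path.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional

from . import __version__
from .classifier import save_model, train_classifier
from .config import RunConfig
from .data_io import (
    read_chrom_sizes,
    read_expression_pairs,
    read_feature_table,
    read_intervals,
    read_label_sets,
    read_mutations,
    write_feature_metadata,
    write_feature_table,
    write_predictions,
)
from .evaluation import labelled_arrays, run_cv
from .laplacian import select_features
from .ranking import rank_candidates
from .resample import smote_oversample
from .validation import ValidationReport, build_validation_report

logger = logging.getLogger(__name__)


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage


@dataclass
class RunManifest:
    config: dict
    seed: int
    version: str = __version__
    inputs: Dict[str, str] = field(default_factory=dict)   # path -> sha256
    stages: List[dict] = field(default_factory=list)       # name, seconds
    outputs: Dict[str, str] = field(default_factory=dict)  # label -> path

    def to_dict(self) -> dict:
        return {
            "version": self.version,
            "seed": self.seed,
            "config": self.config,
            "inputs": self.inputs,
            "stages": self.stages,
            "outputs": self.outputs,
        }

    def write(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1, default=str)


def sha256_of(path: str | Path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(1 << 20), b""):
            h.update(chunk)
    return h.hexdigest()


def run_training_pipeline(
    config: RunConfig,
    features_path: str | Path,
    pos_path: str | Path,
    neg_path: str | Path,
    outdir: str | Path,
) -> RunManifest:
    """select-features -> cv -> final train -> predict, under one config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = RunManifest(config=config.to_dict(), seed=config.seed)
    for p in (features_path, pos_path, neg_path):
        manifest.inputs[str(p)] = sha256_of(p)

    def stage(name, fn):
        t0 = time.perf_counter()
        try:
            result = fn()
        except Exception as exc:
            manifest.stages.append({"stage": name, "status": "failed"})
            manifest.write(outdir / "manifest.json")
            raise StageError(name, exc) from exc
        manifest.stages.append(
            {"stage": name, "status": "ok",
             "seconds": round(time.perf_counter() - t0, 3)}
        )
        logger.info("stage %s done (%.1fs)", name, time.perf_counter() - t0)
        return result

    # 1. feature selection
    def _select():
        table = read_feature_table(features_path)
        reduced, scores, partitions = select_features(table, config)
        write_feature_table(reduced, outdir / "reduced.tsv")
        write_feature_metadata(reduced, outdir / "reduced.meta.tsv")
        part_of = {}
        for part in partitions.values():
            for n in part.lower:
                part_of[n] = "lower"
            for n in part.middle:
                part_of[n] = "middle"
            for n in part.upper:
                part_of[n] = "upper"
        with open(outdir / "scores.tsv", "w") as fh:
            fh.write("feature\tcategory\tscore\tpart\n")
            for s in scores:
                fh.write(f"{s.name}\t{s.category}\t{s.score:.6g}\t{part_of[s.name]}\n")
        return table, reduced

    table, reduced = stage("select_features", _select)
    manifest.outputs["reduced"] = str(outdir / "reduced.tsv")
    manifest.outputs["scores"] = str(outdir / "scores.tsv")

    labels = read_label_sets(pos_path, neg_path, reduced)
    n_unknown = len(labels.unknown)
    logger.info(
        "labels: %d positive, %d negative, %d unknown",
        len(labels.positive), len(labels.negative), n_unknown,
    )

    # 2. cross-validation
    def _cv():
        report = run_cv(reduced, labels, config)
        with open(outdir / "cv_report.json", "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
        return report

    cv_report = stage("cv", _cv)
    manifest.outputs["cv_report"] = str(outdir / "cv_report.json")

    # 3. final training on all labelled genes (SMOTE as in CV)
    def _train():
        X, y, _ = labelled_arrays(reduced, labels)
        if config.smote:
            rs = smote_oversample(
                X, y, k=config.smote_k,
                target_ratio=config.smote_target_ratio,
                rng_seed=config.seed,
            )
            X, y = rs.values, rs.labels
        bc = config.booster
        bc.seed = config.seed
        model = train_classifier(X, y, bc, reduced.feature_names)
        save_model(model, outdir / "model.ubj")
        return model

    model = stage("final_train", _train)
    manifest.outputs["model"] = str(outdir / "model.ubj")

    # 4. prediction on the unknown remainder
    def _predict():
        unknown_ids = [g for g in reduced.gene_ids if g in labels.unknown]
        if not unknown_ids:
            logger.warning("no unknown genes to predict")
            write_predictions([], outdir / "predictions.tsv")
            return []
        unk = reduced.subset_genes(unknown_ids)
        records = rank_candidates(
            model, unk, config.decision_threshold,
            training_ids=labels.positive | labels.negative,
        )
        write_predictions(records, outdir / "predictions.tsv")
        return records

    records = stage("predict", _predict)
    manifest.outputs["predictions"] = str(outdir / "predictions.tsv")
    manifest.write(outdir / "manifest.json")
    logger.info(
        "cv mean AUC %.3f; %d candidates of %d unknown",
        cv_report.mean_auc, sum(r.candidate for r in records), len(records),
    )
    return manifest


def run_validation_pipeline(
    config: RunConfig,
    candidate_ids: List[str],
    pos_ids: List[str],
    neg_ids: List[str],
    lnc_bed: str | Path,
    cancer_bed: str | Path,
    mutations_path: str | Path,
    expr_path: str | Path,
    chrom_sizes_path: str | Path,
    report_path: Optional[str | Path] = None,
) -> ValidationReport:
    """Compute the mutation / distance / DE battery for three gene sets."""
    for name, p in [("lnc-bed", lnc_bed), ("cancer-bed", cancer_bed),
                    ("mutations", mutations_path), ("expr", expr_path),
                    ("chrom-sizes", chrom_sizes_path)]:
        if not Path(p).exists():
            raise FileNotFoundError(f"missing genome input {name}: {p}")
    lnc = read_intervals(lnc_bed)
    by_id = {iv.gene_id: iv for iv in lnc}

    def pick(ids, label):
        found = [by_id[g] for g in ids if g in by_id]
        if len(found) < len(ids):
            logger.warning("%d %s ids have no interval", len(ids) - len(found), label)
        return found

    gene_sets = {
        "positive": pick(pos_ids, "positive"),
        "negative": pick(neg_ids, "negative"),
        "predicted": pick(candidate_ids, "predicted"),
    }
    gene_sets = {k: v for k, v in gene_sets.items() if v}
    report = build_validation_report(
        gene_sets,
        cancer_genes=read_intervals(cancer_bed),
        mutations=read_mutations(mutations_path),
        expr=read_expression_pairs(expr_path),
        chrom_sizes=read_chrom_sizes(chrom_sizes_path),
        rng_seed=config.seed,
    )
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(report.to_dict(), fh, indent=1)
    return report
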