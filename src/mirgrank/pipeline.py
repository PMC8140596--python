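"""End-to-end pipeline: configuration, the three-file output contract,
and external-dataset validation.

A full run reads the paired tables, preprocesses them, performs the MCCV
loop and writes three result files: the aggregated miRNA ranking, the
aggregated gene ranking, and the per-depth performance summary.  The
resolved configuration and per-iteration artifacts are written alongside so
every stochastic step can be audited and the run reproduced bit-identically.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregate import (
    AggregatedRanking,
    aggregate_genes,
    aggregate_mirnas,
    association_scores,
)
from .errors import DataError, ParameterError
from .io_preprocess import (
    ExpressionMatrix,
    PairedDataset,
    PreprocessOptions,
    align_pair,
    preprocess_pair,
    read_expression_table,
)
from .mccv import MccvConfig, performance_summary, run_mccv
from .ranking import MetricSet, compute_metrics, make_classifier, binary_labels
from .topj import auc as roc_auc
from .topj import positive_scores

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Everything a full run needs; serializable to/from a single YAML file."""

    genes_path: str = ""
    mirna_path: str = ""
    out_dir: str = "mirgrank_out"
    id_column: str | None = None
    class_column: str | None = None
    normalization: str = "log2p1_zscore"
    prevalence: bool = False
    prevalence_min_value: float = 1.0
    prevalence_min_fraction: float = 0.5
    mccv: MccvConfig = field(default_factory=MccvConfig)

    def to_yaml(self, path) -> None:
        payload = dataclasses.asdict(self)
        Path(path).write_text(yaml.safe_dump(payload, sort_keys=False))

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        mccv = MccvConfig(**payload.pop("mccv", {}))
        return cls(mccv=mccv, **payload)

    def preprocess_options(self) -> PreprocessOptions:
        return PreprocessOptions(
            normalization=self.normalization,
            prevalence=self.prevalence,
            prevalence_min_value=self.prevalence_min_value,
            prevalence_min_fraction=self.prevalence_min_fraction,
        )


@dataclass
class RunResult:
    """In-memory results of a full run plus the paths written."""

    mirna_ranking: AggregatedRanking
    gene_ranking: AggregatedRanking
    performance: pd.DataFrame
    records: list
    pair: PairedDataset
    paths: dict


def load_pair(config: RunConfig) -> PairedDataset:
    genes = read_expression_table(config.genes_path, config.id_column, config.class_column)
    mirna = read_expression_table(config.mirna_path, config.id_column, config.class_column)
    return align_pair(genes, mirna)


def run_pipeline(config: RunConfig, pair: PairedDataset | None = None) -> RunResult:
    """Full workflow; returns results and writes the three output files.

    Output files: ``mirna_ranking.tsv`` (miRNA, Score (p-value), Targets,
    #Genes), ``gene_ranking.tsv`` (gene, p-value, supporting miRNAs) and
    ``performance.tsv`` (per-depth mean +/- sd test metrics).  The resolved
    config, association scores and per-iteration tables are written too.
    """
    if pair is None:
        pair = load_pair(config)
    pair = preprocess_pair(pair, config.preprocess_options())
    records = run_mccv(pair, config.mccv)

    mirna_ranking = aggregate_mirnas(records, pair.mirna.feature_ids)
    gene_ranking = aggregate_genes(records, pair.genes.feature_ids)
    performance = performance_summary(records)
    assoc = association_scores(records, depth=config.mccv.j_max)

    out = Path(config.out_dir)
    iter_dir = out / "iterations"
    iter_dir.mkdir(parents=True, exist_ok=True)
    paths = {
        "mirna_ranking": out / "mirna_ranking.tsv",
        "gene_ranking": out / "gene_ranking.tsv",
        "performance": out / "performance.tsv",
        "association_scores": out / "association_scores.tsv",
        "config": out / "resolved_config.yaml",
        "iterations": iter_dir,
    }
    mirna_ranking.write(paths["mirna_ranking"])
    gene_ranking.write(paths["gene_ranking"])
    performance.to_csv(paths["performance"], sep="\t", index=False, float_format="%.6g")
    assoc.write(paths["association_scores"])
    config.to_yaml(paths["config"])
    seeds = []
    for record in records:
        seeds.append(
            {"iteration": record.index, "seed": record.seed, "empty": record.empty,
             "n_groups": 0 if record.groups is None else len(record.groups)}
        )
        if record.score_table is not None:
            record.score_table.write(iter_dir / f"iteration_{record.index:03d}_groups.tsv")
    pd.DataFrame(seeds).to_csv(iter_dir / "seeds.tsv", sep="\t", index=False)
    logger.info("run_pipeline: wrote outputs under %s", out)
    return RunResult(
        mirna_ranking=mirna_ranking,
        gene_ranking=gene_ranking,
        performance=performance,
        records=records,
        pair=pair,
        paths=paths,
    )


def _train_eval_genes(
    train_genes: ExpressionMatrix,
    external: ExpressionMatrix,
    gene_list: list,
    classifier: str,
    seed: int,
    positive_label: str,
) -> tuple:
    x_train = train_genes.values[gene_list].to_numpy(dtype=float)
    x_ext = external.values[gene_list].to_numpy(dtype=float)
    y_train = binary_labels(train_genes.classes, positive_label)
    y_ext = binary_labels(external.classes, positive_label)
    model = make_classifier(classifier, seed)
    model.fit(x_train, y_train)
    pred = model.predict(x_ext)
    metrics = compute_metrics(
        tp=int(((pred == 1) & (y_ext == 1)).sum()),
        fp=int(((pred == 1) & (y_ext == 0)).sum()),
        tn=int(((pred == 0) & (y_ext == 0)).sum()),
        fn=int(((pred == 0) & (y_ext == 1)).sum()),
    )
    return metrics, roc_auc(positive_scores(model, x_ext), y_ext)


def external_validation(
    train_pair: PairedDataset,
    external_genes: ExpressionMatrix,
    gene_list_depth: int,
    config: MccvConfig | None = None,
    gene_ranking: AggregatedRanking | None = None,
    random_baseline_repeats: int = 0,
    seed: int = 0,
) -> dict:
    """Train on one dataset's significant genes, test on an external matrix.

    Runs the full MCCV + aggregation on ``train_pair`` (unless a precomputed
    ``gene_ranking`` is supplied), truncates the significant-gene list to
    ``gene_list_depth``, trains a classifier on the training genes restricted
    to that list, and evaluates on ``external_genes``.  When
    ``random_baseline_repeats`` > 0, also evaluates size-matched random gene
    lists and reports their metric averages -- the comparison that shows the
    significant list is more informative than chance.
    """
    config = config or MccvConfig()
    if gene_ranking is None:
        records = run_mccv(train_pair, config)
        gene_ranking = aggregate_genes(records, train_pair.genes.feature_ids)
    top = [g for g in gene_ranking.items][:gene_list_depth]
    present = [g for g in top if g in external_genes.values.columns]
    if len(present) < 0.5 * len(top):
        missing = sorted(set(top) - set(present))
        raise DataError(f"fewer than half of the listed genes present externally: missing {missing}")
    result = {"depth": gene_list_depth, "genes": present}
    metrics, area = _train_eval_genes(
        train_pair.genes, external_genes, present, config.classifier, seed,
        config.positive_label,
    )
    result["metrics"] = metrics
    result["auc"] = area
    if random_baseline_repeats > 0:
        pool = [
            g for g in train_pair.genes.feature_ids if g in external_genes.values.columns
        ]
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(random_baseline_repeats):
            pick = list(rng.choice(pool, size=min(len(present), len(pool)), replace=False))
            m, a = _train_eval_genes(
                train_pair.genes, external_genes, pick, config.classifier,
                int(rng.integers(2**31)), config.positive_label,
            )
            reps.append((m, a))
        result["random_metrics"] = MetricSet(
            tp=0, fp=0, tn=0, fn=0,
            accuracy=float(np.mean([m.accuracy for m, _ in reps])),
            sensitivity=float(np.mean([m.sensitivity for m, _ in reps])),
            specificity=float(np.mean([m.specificity for m, _ in reps])),
            recall=float(np.mean([m.recall for m, _ in reps])),
            precision=float(np.mean([m.precision for m, _ in reps])),
            f_measure=float(np.mean([m.f_measure for m, _ in reps])),
            cohens_kappa=float(np.mean([m.cohens_kappa for m, _ in reps])),
        )
        result["random_auc"] = float(np.nanmean([a for _, a in reps]))
    return result
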