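"""Monte-Carlo cross-validation driver: the outer loop of the method.

Each of ``n_iterations`` (default 100) iterations draws a fresh 1:2
under-sampled, 90/10 stratified train/test partition, runs the whole
differential-expression -> correlation -> grouping -> ranking chain on the
training part only, and evaluates the cumulative top-j models on the held-out
test part.  Per-iteration miRNA and gene rankings feed the aggregation stage.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import DataError, ParameterError, PipelineError
from .grouping import TargetGeneGroups, build_groups, correlation_matrix
from .io_preprocess import ExpressionMatrix, PairedDataset, de_filter_ttest
from .ranking import GroupScoreTable, rank_groups
from .topj import evaluate_top_groups

logger = logging.getLogger(__name__)


@dataclass
class MccvConfig:
    """All tunable parameters of the outer loop, with their standard defaults.

    Defaults mirror the published protocol: 100 iterations of a 90/10
    stratified split, majority-class under-sampling at 1:2, correlation
    threshold -0.6, DE filter at alpha 0.05, internal group scoring with 5
    repeats of an 80:20 split, cumulative models to depth j_max = 10.
    """

    n_iterations: int = 100
    train_fraction: float = 0.9
    undersample_ratio: float = 2.0
    master_seed: int = 0
    j_max: int = 10
    classifier: str = "random_forest"
    correlation_threshold: float = -0.6
    alpha: float = 0.05
    internal_repeats: int = 5
    internal_train_fraction: float = 0.8
    positive_label: str = "pos"
    ttest_variant: str = "welch"
    metric_aggregate: str = "micro"
    undersample_scope: str = "all"  # "all" or "train_only"
    max_empty_fraction: float = 0.5

    def __post_init__(self) -> None:
        if not (0.0 < self.train_fraction < 1.0):
            raise ParameterError("train_fraction must be in (0, 1)")
        if self.undersample_ratio < 1.0:
            raise ParameterError("undersample_ratio must be >= 1")
        if self.n_iterations < 1:
            raise ParameterError("n_iterations must be >= 1")
        if self.undersample_scope not in ("all", "train_only"):
            raise ParameterError("undersample_scope must be 'all' or 'train_only'")


@dataclass
class IterationRecord:
    """Everything one MCCV iteration produced.

    ``mirna_ranking`` is the ordered miRNA list (best first);
    ``gene_ranking`` maps each gene to its inherited rank -- the rank of the
    best-ranked group containing it.  ``empty`` marks iterations where no
    miRNA-mRNA association passed the threshold.
    """

    index: int
    seed: int
    empty: bool
    mirna_ranking: list
    gene_ranking: dict
    topj_results: list
    score_table: GroupScoreTable | None
    groups: TargetGeneGroups | None
    train_sample_ids: list
    test_sample_ids: list


def iteration_seed(master_seed: int, iteration: int) -> int:
    """Stable per-iteration seed derived from the master seed (below 2^31)."""
    return int(
        np.random.SeedSequence([int(master_seed), int(iteration)]).generate_state(1)[0]
        % (2**31)
    )


def undersample(matrix: ExpressionMatrix, ratio: float = 2.0, seed: int = 0) -> ExpressionMatrix:
    """Down-sample the majority class to at most ``ratio`` x the minority.

    The minority class is kept whole; majority samples are drawn without
    replacement.  Original sample order is preserved.  Deterministic given
    ``seed``.
    """
    if ratio < 1.0:
        raise ParameterError("undersample ratio must be >= 1")
    counts = matrix.class_counts()
    if len(counts) != 2:
        raise DataError("undersample requires exactly two classes")
    minority_label = counts.idxmin()
    majority_label = counts.idxmax()
    if minority_label == majority_label:  # equal counts: value_counts order tie
        return matrix
    cap = int(np.floor(ratio * counts[minority_label]))
    majority_ids = [s for s, c in matrix.classes.items() if c == majority_label]
    if len(majority_ids) <= cap:
        return matrix
    rng = np.random.default_rng(seed)
    kept_majority = set(rng.choice(majority_ids, size=cap, replace=False))
    keep = [
        s
        for s, c in matrix.classes.items()
        if c == minority_label or s in kept_majority
    ]
    return matrix.subset_samples(keep)


def stratified_split(
    matrix: ExpressionMatrix, train_fraction: float = 0.9, seed: int = 0
) -> tuple:
    """Disjoint, exhaustive per-class split into (train, test).

    Each class contributes floor(train_fraction * n_class) samples to the
    training part (clamped so both parts keep at least one sample per class);
    the remainder goes to the test part.
    """
    if not (0.0 < train_fraction < 1.0):
        raise ParameterError("train_fraction must be in (0, 1)")
    rng = np.random.default_rng(seed)
    train_ids: list = []
    test_ids: list = []
    for label, count in matrix.class_counts().sort_index().items():
        if count < 2:
            raise DataError(f"class '{label}' has {count} sample(s); cannot appear in both parts")
        ids = [s for s, c in matrix.classes.items() if c == label]
        n_train = int(np.floor(train_fraction * count))
        n_train = min(max(n_train, 1), count - 1)
        perm = rng.permutation(len(ids))
        train_ids.extend(ids[i] for i in perm[:n_train])
        test_ids.extend(ids[i] for i in perm[n_train:])
    # preserve original sample order inside each part
    order = {s: i for i, s in enumerate(matrix.sample_ids)}
    train_ids.sort(key=order.__getitem__)
    test_ids.sort(key=order.__getitem__)
    return matrix.subset_samples(train_ids), matrix.subset_samples(test_ids)


def inherited_gene_ranks(table: GroupScoreTable, groups: TargetGeneGroups) -> dict:
    """Each gene inherits the rank of its miRNA group; best rank wins on ties."""
    ranks: dict = {}
    for rank, mirna in enumerate(table.ranked_mirnas, start=1):
        for gene in groups[mirna]:
            if gene not in ranks:
                ranks[gene] = rank
    return ranks


def run_iteration(pair: PairedDataset, config: MccvConfig, index: int) -> IterationRecord:
    """One MCCV iteration: under-sample, split, train-side chain, test-side eval."""
    seed = iteration_seed(config.master_seed, index)
    working = pair
    if config.undersample_scope == "all":
        sampled = undersample(working.genes, config.undersample_ratio, seed)
        working = working.subset_samples(sampled.sample_ids)
    train_g, test_g = stratified_split(working.genes, config.train_fraction, seed)
    train_ids, test_ids = train_g.sample_ids, test_g.sample_ids
    if config.undersample_scope == "train_only":
        sampled = undersample(working.genes.subset_samples(train_ids),
                              config.undersample_ratio, seed)
        train_ids = sampled.sample_ids

    train = working.subset_samples(train_ids)
    test_genes = working.genes.subset_samples(test_ids)

    empty_record = IterationRecord(
        index=index, seed=seed, empty=True, mirna_ranking=[], gene_ranking={},
        topj_results=[], score_table=None, groups=None,
        train_sample_ids=train_ids, test_sample_ids=test_ids,
    )
    genes_de = de_filter_ttest(train.genes, config.alpha, config.ttest_variant)
    mirna_de = de_filter_ttest(train.mirna, config.alpha, config.ttest_variant)
    if genes_de.n_features == 0 or mirna_de.n_features == 0:
        logger.warning("iteration %d: no features survive the DE filter", index)
        return empty_record
    corr = correlation_matrix(PairedDataset(genes_de, mirna_de))
    try:
        groups = build_groups(corr, config.correlation_threshold)
    except PipelineError:
        logger.warning("iteration %d: no miRNA-mRNA associations at threshold", index)
        return empty_record
    table = rank_groups(
        genes_de,
        groups,
        config.positive_label,
        r=config.internal_repeats,
        f=config.internal_train_fraction,
        classifier=config.classifier,
        seed=seed,
        aggregate=config.metric_aggregate,
    )
    topj = evaluate_top_groups(
        table, groups, train.genes, test_genes,
        j_max=config.j_max, classifier=config.classifier, seed=seed,
        positive_label=config.positive_label,
    )
    return IterationRecord(
        index=index,
        seed=seed,
        empty=False,
        mirna_ranking=table.ranked_mirnas,
        gene_ranking=inherited_gene_ranks(table, groups),
        topj_results=topj,
        score_table=table,
        groups=groups,
        train_sample_ids=train_ids,
        test_sample_ids=test_ids,
    )


def run_mccv(pair: PairedDataset, config: MccvConfig) -> list:
    """All MCCV iterations; raises if more than half find no associations."""
    records = [run_iteration(pair, config, i) for i in range(config.n_iterations)]
    n_empty = sum(r.empty for r in records)
    if n_empty > config.max_empty_fraction * len(records):
        raise PipelineError(
            f"{n_empty}/{len(records)} iterations found no miRNA-mRNA associations "
            f"at threshold {config.correlation_threshold}; no reliable ranking possible"
        )
    return records


def performance_summary(records: list) -> pd.DataFrame:
    """Mean +/- sd of the top-j test metrics across non-empty iterations."""
    rows = []
    for record in records:
        for res in record.topj_results:
            rows.append(
                {
                    "j": res.j,
                    "#Genes": res.gene_count,
                    "Accuracy": res.metrics.accuracy,
                    "Sensitivity": res.metrics.sensitivity,
                    "Specificity": res.metrics.specificity,
                    "AUC": res.auc,
                }
            )
    if not rows:
        return pd.DataFrame(
            columns=["j", "#Genes", "Accuracy", "Sensitivity", "Specificity", "AUC"]
        )
    frame = pd.DataFrame(rows)
    summary = frame.groupby("j").agg(["mean", "std"])
    summary.columns = [f"{metric} ({stat})" for metric, stat in summary.columns]
    return summary.reset_index()
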