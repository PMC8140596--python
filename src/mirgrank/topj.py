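"""Cumulative top-j models: train on the genes of the j best-ranked groups.

For j = 1..j_max (default 10) a classifier is trained on the union of the
genes belonging to the top j ranked groups, using training samples only, and
evaluated on held-out test samples.  AUC is the probability that a random
case scores above a random control (Mann-Whitney scaling, ties counted 1/2).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import roc_auc_score

from .errors import DataError, ParameterError
from .grouping import TargetGeneGroups
from .io_preprocess import ExpressionMatrix
from .ranking import GroupScoreTable, MetricSet, binary_labels, compute_metrics, make_classifier

logger = logging.getLogger(__name__)

DEFAULT_J_MAX = 10


@dataclass
class TopJResult:
    """Test-set performance of the model built on the top-j group genes."""

    j: int
    gene_count: int
    metrics: MetricSet
    auc: float


def genes_of_top_j(table: GroupScoreTable, groups: TargetGeneGroups, j: int) -> list:
    """Deduplicated union of the gene lists of the top j ranked groups.

    Order is first appearance walking the ranking.  j beyond the number of
    ranked groups is clamped with a warning.
    """
    if j < 1:
        raise ParameterError("j must be >= 1")
    ranked = table.ranked_mirnas
    if j > len(ranked):
        logger.warning("genes_of_top_j: j=%d clamped to %d available groups", j, len(ranked))
        j = len(ranked)
    seen: dict = {}
    for mirna in ranked[:j]:
        for gene in groups[mirna]:
            seen.setdefault(gene, None)
    return list(seen)


def auc(scores, labels) -> float:
    """Area under the ROC curve from per-sample positive-class scores.

    Equals the Mann-Whitney U statistic scaled to [0, 1] with ties counted
    1/2; invariant to monotone transforms of the scores.  Returns NaN when
    only one class is present (undefined).
    """
    labels = np.asarray(labels, dtype=int)
    scores = np.asarray(scores, dtype=float)
    if labels.shape != scores.shape:
        raise ParameterError("scores and labels must have equal length")
    if len(np.unique(labels)) < 2:
        return float("nan")
    return float(roc_auc_score(labels, scores))


def positive_scores(model, x: np.ndarray) -> np.ndarray:
    """Positive-class score per sample: probability if available, else margin."""
    if hasattr(model, "predict_proba"):
        idx = int(np.where(model.classes_ == 1)[0][0])
        return model.predict_proba(x)[:, idx]
    return np.asarray(model.decision_function(x), dtype=float)


def fit_and_eval(
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    gene_list: list,
    classifier: str = "random_forest",
    seed: int = 0,
    positive_label: str = "pos",
    j: int = 0,
) -> TopJResult:
    """Train on ``train`` restricted to ``gene_list``; score on ``test``.

    Test samples must be disjoint from every upstream computation (filtering,
    correlation, grouping, ranking) -- this function only consumes the split.
    Genes absent from either matrix are dropped from both with a warning.
    """
    if not gene_list:
        raise ParameterError("gene_list is empty")
    usable = [
        g for g in gene_list if g in train.values.columns and g in test.values.columns
    ]
    if not usable:
        raise DataError("no gene of gene_list present in both train and test matrices")
    if len(usable) < len(gene_list):
        logger.warning(
            "fit_and_eval: %d/%d genes absent from train or test; dropped",
            len(gene_list) - len(usable),
            len(gene_list),
        )
    x_train = train.values[usable].to_numpy(dtype=float)
    x_test = test.values[usable].to_numpy(dtype=float)
    y_train = binary_labels(train.classes, positive_label)
    y_test = binary_labels(test.classes, positive_label)
    model = make_classifier(classifier, seed)
    model.fit(x_train, y_train)
    pred = model.predict(x_test)
    metrics = compute_metrics(
        tp=int(((pred == 1) & (y_test == 1)).sum()),
        fp=int(((pred == 1) & (y_test == 0)).sum()),
        tn=int(((pred == 0) & (y_test == 0)).sum()),
        fn=int(((pred == 0) & (y_test == 1)).sum()),
    )
    area = auc(positive_scores(model, x_test), y_test)
    return TopJResult(j=j, gene_count=len(usable), metrics=metrics, auc=area)


def evaluate_top_groups(
    table: GroupScoreTable,
    groups: TargetGeneGroups,
    train: ExpressionMatrix,
    test: ExpressionMatrix,
    j_max: int = DEFAULT_J_MAX,
    classifier: str = "random_forest",
    seed: int = 0,
    positive_label: str = "pos",
) -> list:
    """TopJResult for every depth j = 1..min(j_max, #groups)."""
    results = []
    depth = min(j_max, len(table.ranked_mirnas))
    for j in range(1, depth + 1):
        gene_list = genes_of_top_j(table, groups, j)
        results.append(
            fit_and_eval(
                train, test, gene_list,
                classifier=classifier, seed=seed + j, positive_label=positive_label, j=j,
            )
        )
    return results
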