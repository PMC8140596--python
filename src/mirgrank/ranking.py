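"""Scoring miRNA target-gene groups by internal hold-out classification.

Each group is scored by how well a classifier trained only on that group's
genes separates the two classes: ``r`` (default 5) independent stratified
80:20 splits of the training data, confusion counts pooled across repeats,
and the seven summary metrics computed from the pooled table.  Groups are
then ranked by mean accuracy.
"""

from __future__ import annotations

import logging
import zlib
from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedShuffleSplit
from sklearn.svm import SVC

from .errors import DataError, ParameterError
from .grouping import TargetGeneGroups
from .io_preprocess import ExpressionMatrix

logger = logging.getLogger(__name__)

CLASSIFIERS = ("random_forest", "svm")
METRIC_COLUMNS = (
    "Accuracy",
    "Sensitivity",
    "Specificity",
    "Recall",
    "Precision",
    "F-measure",
    "Cohen's kappa",
)


@dataclass
class MetricSet:
    """Confusion counts and the seven derived classification metrics.

    A metric whose denominator is zero is reported as 0.0 and its name is
    recorded in ``undefined``, so every group always gets a complete row.
    """

    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    sensitivity: float
    specificity: float
    recall: float
    precision: float
    f_measure: float
    cohens_kappa: float
    undefined: tuple = ()

    def as_row(self) -> dict:
        return {
            "Accuracy": self.accuracy,
            "Sensitivity": self.sensitivity,
            "Specificity": self.specificity,
            "Recall": self.recall,
            "Precision": self.precision,
            "F-measure": self.f_measure,
            "Cohen's kappa": self.cohens_kappa,
        }


def compute_metrics(tp: int, fp: int, tn: int, fn: int) -> MetricSet:
    """All seven metrics from a 2x2 confusion table.

    accuracy=(TP+TN)/total, sensitivity=recall=TP/(TP+FN),
    specificity=TN/(TN+FP), precision=TP/(TP+FP), F-measure=harmonic mean of
    precision and recall, and Cohen's kappa=(p_o-p_e)/(1-p_e) with p_e the
    chance agreement of the marginals.
    """
    if min(tp, fp, tn, fn) < 0:
        raise ParameterError("confusion counts must be non-negative")
    total = tp + fp + tn + fn
    if total == 0:
        raise ParameterError("confusion table is empty")
    undefined = []

    def ratio(num, den, name):
        if den == 0:
            undefined.append(name)
            return 0.0
        return num / den

    accuracy = (tp + tn) / total
    sensitivity = ratio(tp, tp + fn, "sensitivity")
    specificity = ratio(tn, tn + fp, "specificity")
    precision = ratio(tp, tp + fp, "precision")
    f_measure = ratio(2 * precision * sensitivity, precision + sensitivity, "f_measure")
    p_e = ((tp + fn) * (tp + fp) + (tn + fp) * (tn + fn)) / total**2
    if p_e == 1.0:
        undefined.append("cohens_kappa")
        kappa = 0.0
    else:
        kappa = (accuracy - p_e) / (1.0 - p_e)
    return MetricSet(
        tp=tp,
        fp=fp,
        tn=tn,
        fn=fn,
        accuracy=accuracy,
        sensitivity=sensitivity,
        specificity=specificity,
        recall=sensitivity,
        precision=precision,
        f_measure=f_measure,
        cohens_kappa=kappa,
        undefined=tuple(undefined),
    )


def make_classifier(name: str, seed: int):
    """Instantiate the scoring classifier with fixed hyperparameters.

    Random forest: 100 trees, unrestricted depth.  SVM: linear kernel,
    C=1 (decision-function scores are used where probabilities are needed).
    """
    if name == "random_forest":
        return RandomForestClassifier(n_estimators=100, random_state=seed)
    if name == "svm":
        return SVC(kernel="linear", C=1.0, random_state=seed)
    raise ParameterError(f"unknown classifier '{name}'; choose from {CLASSIFIERS}")


def binary_labels(classes: pd.Series, positive_label: str) -> np.ndarray:
    """Encode the case class as 1 and the control class as 0."""
    labels = set(classes.unique())
    if positive_label not in labels:
        raise DataError(f"positive label '{positive_label}' not among class labels {labels}")
    return (classes == positive_label).to_numpy(dtype=int)


def make_sub_data(genes: ExpressionMatrix, group: list) -> ExpressionMatrix:
    """Column-subset the gene matrix to a group's genes, labels untouched."""
    present = [g for g in group if g in genes.values.columns]
    if not present:
        raise DataError("no group gene present in the expression matrix")
    if len(present) < len(group):
        logger.warning(
            "make_sub_data: %d/%d group genes absent from matrix",
            len(group) - len(present),
            len(group),
        )
    return genes.subset_features(present)


def score_group(
    sub_data: ExpressionMatrix,
    positive_label: str,
    r: int = 5,
    f: float = 0.8,
    classifier: str = "random_forest",
    seed: int = 0,
    aggregate: str = "micro",
) -> MetricSet:
    """Score one group: r stratified f:(1-f) hold-outs, metrics from pooled counts.

    ``micro`` aggregation (default) pools the confusion counts of all repeats
    before computing metrics -- robust when test folds are tiny.  ``macro``
    averages per-repeat metrics instead.  Deterministic given ``seed``.
    """
    if aggregate not in ("micro", "macro"):
        raise ParameterError(f"unknown aggregation '{aggregate}'")
    sub_data.require_two_classes()
    y = binary_labels(sub_data.classes, positive_label)
    x = sub_data.values.to_numpy(dtype=float)
    splitter = StratifiedShuffleSplit(n_splits=r, train_size=f, random_state=seed)
    counts = np.zeros(4, dtype=int)  # tp, fp, tn, fn
    per_repeat = []
    for k, (train_idx, test_idx) in enumerate(splitter.split(x, y)):
        model = make_classifier(classifier, seed + k)
        model.fit(x[train_idx], y[train_idx])
        pred = model.predict(x[test_idx])
        truth = y[test_idx]
        rep = np.array(
            [
                int(((pred == 1) & (truth == 1)).sum()),
                int(((pred == 1) & (truth == 0)).sum()),
                int(((pred == 0) & (truth == 0)).sum()),
                int(((pred == 0) & (truth == 1)).sum()),
            ]
        )
        counts += rep
        per_repeat.append(rep)
    if aggregate == "micro":
        return compute_metrics(*[int(c) for c in counts])
    reps = [compute_metrics(*[int(c) for c in rep]) for rep in per_repeat]
    mean = lambda attr: float(np.mean([getattr(m, attr) for m in reps]))
    return MetricSet(
        tp=int(counts[0]),
        fp=int(counts[1]),
        tn=int(counts[2]),
        fn=int(counts[3]),
        accuracy=mean("accuracy"),
        sensitivity=mean("sensitivity"),
        specificity=mean("specificity"),
        recall=mean("recall"),
        precision=mean("precision"),
        f_measure=mean("f_measure"),
        cohens_kappa=mean("cohens_kappa"),
        undefined=tuple(sorted({u for m in reps for u in m.undefined})),
    )


@dataclass
class GroupScoreTable:
    """Per-group metrics sorted into the group ranking.

    Rows are ordered descending by accuracy; ties broken by higher F-measure,
    then larger group, then miRNA id.  ``ranked_mirnas`` is the ranking the
    aggregation stage consumes (rank 1 = best).
    """

    rows: list  # list of (mirna_id, MetricSet, gene_list)

    @property
    def ranked_mirnas(self) -> list:
        return [mirna for mirna, _, _ in self.rows]

    def gene_lists(self) -> dict:
        return {mirna: genes for mirna, _, genes in self.rows}

    def to_frame(self) -> pd.DataFrame:
        frame = pd.DataFrame(
            [{"miRNA": mirna, **metrics.as_row(), "#Genes": len(genes)}
             for mirna, metrics, genes in self.rows]
        )
        return frame[["miRNA", *METRIC_COLUMNS, "#Genes"]]

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def rank_groups(
    genes: ExpressionMatrix,
    groups: TargetGeneGroups,
    positive_label: str,
    r: int = 5,
    f: float = 0.8,
    classifier: str = "random_forest",
    seed: int = 0,
    aggregate: str = "micro",
) -> GroupScoreTable:
    """Score every group and sort into the ranking table.

    Groups whose genes are entirely absent from the matrix are skipped with a
    warning.  The per-group scoring seed is derived from ``seed`` and the
    miRNA id so the ranking does not depend on group insertion order.
    """
    scored = []
    for mirna in groups.mirna_ids:
        try:
            sub = make_sub_data(genes, groups[mirna])
        except DataError:
            logger.warning("rank_groups: group %s has no genes in matrix; skipped", mirna)
            continue
        group_seed = int(
            np.random.SeedSequence(
                [seed, zlib.crc32(str(mirna).encode())]
            ).generate_state(1)[0]
            % (2**31)
        )
        metrics = score_group(
            sub, positive_label, r=r, f=f, classifier=classifier, seed=group_seed,
            aggregate=aggregate,
        )
        scored.append((mirna, metrics, sub.feature_ids))
    if not scored:
        raise DataError("no scoreable group")
    scored.sort(
        key=lambda row: (-row[1].accuracy, -row[1].f_measure, -len(row[2]), str(row[0]))
    )
    return GroupScoreTable(scored)
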