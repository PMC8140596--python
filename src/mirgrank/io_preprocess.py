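"""Reading, validation, alignment and filtering of paired expression tables.

The pipeline consumes two sample x feature tables over the same samples: one
for mRNA (gene) expression and one for miRNA expression.  Each table carries a
sample-identifier column, a two-level class column (case/control) and
non-negative normalized expression columns.  Preprocessing runs in a fixed
order: missing-value removal, optional prevalence filtering on the raw scale,
normalization, then (inside the cross-validation loop, on training data only)
a per-feature two-sample t-test filter.
"""

from __future__ import annotations

import csv
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DataError, InputFormatError, ParameterError

logger = logging.getLogger(__name__)

NORMALIZATION_METHODS = ("log2p1_zscore", "zscore", "none")
TTEST_VARIANTS = ("welch", "pooled")


@dataclass
class ExpressionMatrix:
    """Samples x features expression values with per-sample class labels.

    ``values`` is indexed by sample id (rows) and feature id (columns); missing
    measurements are NaN, never silently zero.  ``classes`` shares the sample
    index and holds the (typically two-level) class label of each sample.
    """

    values: pd.DataFrame
    classes: pd.Series

    def __post_init__(self) -> None:
        if not self.values.index.equals(self.classes.index):
            raise DataError("values and class labels are indexed by different samples")
        if self.values.index.has_duplicates:
            dups = self.values.index[self.values.index.duplicated()].unique().tolist()
            raise DataError(f"duplicate sample ids: {dups}")
        if self.values.columns.has_duplicates:
            dups = self.values.columns[self.values.columns.duplicated()].unique().tolist()
            raise DataError(f"duplicate feature ids: {dups}")

    @property
    def sample_ids(self) -> list:
        return self.values.index.tolist()

    @property
    def feature_ids(self) -> list:
        return self.values.columns.tolist()

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def class_counts(self) -> pd.Series:
        return self.classes.value_counts()

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values.loc[sample_ids], self.classes.loc[sample_ids])

    def subset_features(self, feature_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.values[list(feature_ids)], self.classes)

    def require_two_classes(self, min_per_class: int = 2) -> None:
        counts = self.class_counts()
        if len(counts) != 2:
            raise DataError(
                f"expected exactly 2 class labels, found {len(counts)}: {counts.index.tolist()}"
            )
        small = counts[counts < min_per_class]
        if not small.empty:
            raise DataError(
                f"fewer than {min_per_class} samples in class(es) {small.index.tolist()}"
            )


@dataclass
class PairedDataset:
    """Gene and miRNA expression over the same samples, in the same order."""

    genes: ExpressionMatrix
    mirna: ExpressionMatrix

    def __post_init__(self) -> None:
        if self.genes.sample_ids != self.mirna.sample_ids:
            raise DataError("gene and miRNA matrices cover different samples or orders")
        if not self.genes.classes.equals(self.mirna.classes):
            bad = self.genes.classes[self.genes.classes != self.mirna.classes]
            raise DataError(f"class label conflict for sample(s): {bad.index.tolist()}")

    @property
    def sample_ids(self) -> list:
        return self.genes.sample_ids

    @property
    def classes(self) -> pd.Series:
        return self.genes.classes

    def subset_samples(self, sample_ids) -> "PairedDataset":
        return PairedDataset(
            self.genes.subset_samples(sample_ids), self.mirna.subset_samples(sample_ids)
        )


def read_expression_table(
    path,
    id_column: str | None = None,
    class_column: str | None = None,
    min_per_class: int = 2,
) -> ExpressionMatrix:
    """Read a delimited expression table (comma or tab auto-detected).

    The layout is one header row, a sample-id column (default: first column)
    and a class column (default: second column); every remaining column is a
    numeric feature.  Non-numeric expression cells (e.g. "NA") are recorded as
    missing, not as zero.
    """
    try:
        frame = pd.read_csv(path, sep=None, engine="python")
    except (pd.errors.EmptyDataError, csv.Error) as exc:
        raise InputFormatError(f"{path}: file is empty or not a delimited table") from exc
    except FileNotFoundError as exc:
        raise InputFormatError(f"{path}: file not found") from exc
    if frame.shape[1] < 3:
        raise InputFormatError(
            f"{path}: expected id column, class column and >=1 feature column, "
            f"found {frame.shape[1]} column(s)"
        )
    id_column = id_column if id_column is not None else frame.columns[0]
    class_column = class_column if class_column is not None else frame.columns[1]
    for name in (id_column, class_column):
        if name not in frame.columns:
            raise InputFormatError(f"{path}: required column '{name}' is missing")
    if frame.empty:
        raise DataError(f"{path}: no sample rows")

    sample_index = pd.Index(frame[id_column].astype(str), name=id_column)
    classes = pd.Series(frame[class_column].astype(str).values, index=sample_index, name="class")
    feature_cols = [c for c in frame.columns if c not in (id_column, class_column)]
    values = frame[feature_cols].apply(pd.to_numeric, errors="coerce")
    values.index = sample_index

    matrix = ExpressionMatrix(values, classes)
    matrix.require_two_classes(min_per_class)
    return matrix


def align_pair(genes: ExpressionMatrix, mirna: ExpressionMatrix) -> PairedDataset:
    """Restrict both matrices to their shared samples, in a common order.

    The order is the gene matrix's sample order restricted to the
    intersection; class labels are verified to agree per shared sample.
    Idempotent: aligning an aligned pair changes nothing.
    """
    shared = [s for s in genes.sample_ids if s in set(mirna.sample_ids)]
    if not shared:
        raise DataError("no samples shared between the gene and miRNA tables")
    g = genes.subset_samples(shared)
    m = mirna.subset_samples(shared)
    conflicts = g.classes[g.classes != m.classes]
    if not conflicts.empty:
        raise DataError(
            f"class label conflict between tables for sample(s): {conflicts.index.tolist()}"
        )
    pair = PairedDataset(g, m)
    pair.genes.require_two_classes()
    return pair


def remove_missing(matrix: ExpressionMatrix) -> ExpressionMatrix:
    """Drop every feature (column) containing at least one missing value.

    Samples are kept whole: in case/control designs samples are the scarce
    resource, so missingness costs features, not samples.
    """
    keep = matrix.values.columns[matrix.values.notna().all(axis=0)]
    dropped = matrix.n_features - len(keep)
    if len(keep) == 0:
        raise DataError("every feature contains missing values; nothing left to analyse")
    if dropped:
        logger.warning("remove_missing: dropped %d feature(s) with missing values", dropped)
    return matrix.subset_features(keep)


def normalize(matrix: ExpressionMatrix, method: str = "log2p1_zscore") -> ExpressionMatrix:
    """Normalize expression values per feature.

    ``log2p1_zscore``: log2(x+1) then per-feature standardization to mean 0,
    sd 1.  ``zscore``: standardization only.  ``none``: identity.  Constant
    features cannot be standardized and are dropped with a warning.
    """
    if method not in NORMALIZATION_METHODS:
        raise ParameterError(f"unknown normalization method '{method}'")
    if method == "none":
        return matrix
    if matrix.values.isna().any().any():
        raise DataError("normalize requires missing values to be removed first")
    values = matrix.values
    if method == "log2p1_zscore":
        values = np.log2(values + 1.0)
    sd = values.std(axis=0, ddof=1)
    constant = sd.index[(sd == 0) | sd.isna()]
    if len(constant):
        logger.warning(
            "normalize: dropping %d constant feature(s), e.g. %s",
            len(constant),
            constant[:3].tolist(),
        )
        values = values.drop(columns=constant)
        sd = sd.drop(index=constant)
    if values.shape[1] == 0:
        raise DataError("all features constant; nothing left after normalization")
    values = (values - values.mean(axis=0)) / sd
    return ExpressionMatrix(values, matrix.classes)


def prevalence_filter(
    matrix: ExpressionMatrix, min_value: float = 1.0, min_fraction: float = 0.5
) -> ExpressionMatrix:
    """Keep features expressed at >= ``min_value`` in >= ``min_fraction`` of samples.

    Intended for raw-scale (pre-normalization) values; both bounds are
    inclusive, so a feature at exactly the fraction is kept.
    """
    frac = (matrix.values >= min_value).mean(axis=0)
    keep = frac.index[frac >= min_fraction]
    dropped = matrix.n_features - len(keep)
    if dropped:
        logger.info("prevalence_filter: dropped %d low-prevalence feature(s)", dropped)
    return matrix.subset_features(keep)


def ttest_pvalues(matrix: ExpressionMatrix, variant: str = "welch") -> pd.Series:
    """Per-feature two-sample t-test p-values between the two classes."""
    if variant not in TTEST_VARIANTS:
        raise ParameterError(f"unknown t-test variant '{variant}'")
    matrix.require_two_classes()
    labels = matrix.class_counts().index.tolist()
    a = matrix.values[matrix.classes == labels[0]].to_numpy()
    b = matrix.values[matrix.classes == labels[1]].to_numpy()
    with np.errstate(invalid="ignore", divide="ignore"):
        _, p = stats.ttest_ind(a, b, axis=0, equal_var=(variant == "pooled"))
    return pd.Series(p, index=matrix.values.columns, name="p_value")


def de_filter_ttest(
    matrix: ExpressionMatrix, alpha: float = 0.05, variant: str = "welch"
) -> ExpressionMatrix:
    """Keep features differentially expressed between the classes at p <= alpha.

    Features with an undefined test statistic (zero variance in both classes
    with equal means) are dropped with a warning.
    """
    p = ttest_pvalues(matrix, variant=variant)
    undefined = p.index[p.isna()]
    if len(undefined):
        logger.warning(
            "de_filter_ttest: %d feature(s) with undefined t statistic dropped", len(undefined)
        )
    keep = p.index[(p <= alpha).fillna(False)]
    logger.info(
        "de_filter_ttest: retained %d/%d features at alpha=%g", len(keep), matrix.n_features, alpha
    )
    return matrix.subset_features(keep)


@dataclass
class PreprocessOptions:
    """Options for the deterministic (non-CV) part of preprocessing."""

    normalization: str = "log2p1_zscore"
    prevalence: bool = False
    prevalence_min_value: float = 1.0
    prevalence_min_fraction: float = 0.5


def preprocess_pair(pair: PairedDataset, options: PreprocessOptions | None = None) -> PairedDataset:
    """Missing-value removal, optional prevalence filter, then normalization.

    The differential-expression t-test filter is *not* applied here: it runs
    inside the cross-validation loop on training samples only.
    """
    options = options or PreprocessOptions()

    def one(matrix: ExpressionMatrix) -> ExpressionMatrix:
        matrix = remove_missing(matrix)
        if options.prevalence:
            matrix = prevalence_filter(
                matrix, options.prevalence_min_value, options.prevalence_min_fraction
            )
        return normalize(matrix, options.normalization)

    return PairedDataset(one(pair.genes), one(pair.mirna))
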