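"""miRNA x mRNA Pearson correlation and anti-correlated target-gene groups.

A miRNA represses its target mRNAs, so a strongly negative expression
correlation between a miRNA and a gene across samples is taken as evidence of
targeting.  The grouping step turns the miRNA x gene correlation matrix into
an ordered mapping miRNA -> genes with r <= threshold (default -0.6, i.e.
|r| >= 0.6 with r < 0); those groups are the units ranked downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import ParameterError, PipelineError
from .io_preprocess import PairedDataset

logger = logging.getLogger(__name__)

DEFAULT_CORRELATION_THRESHOLD = -0.6


def pearson_r(x, y) -> float:
    """Pearson product-moment correlation of two equal-length vectors.

    Returns NaN for constant input (undefined correlation); callers treat NaN
    as "no association", never as passing a threshold.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ParameterError("pearson_r expects two 1-d vectors of equal length")
    if x.size < 3:
        raise ParameterError("pearson_r requires at least 3 observations")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.sqrt((xc @ xc) * (yc @ yc))
    if denom == 0:
        return float("nan")
    return float(np.clip((xc @ yc) / denom, -1.0, 1.0))


@dataclass
class CorrelationMatrix:
    """miRNA x gene Pearson r values; NaN marks undefined (no association)."""

    r_values: pd.DataFrame  # index: miRNA ids, columns: gene ids

    @property
    def mirna_ids(self) -> list:
        return self.r_values.index.tolist()

    @property
    def gene_ids(self) -> list:
        return self.r_values.columns.tolist()


def correlation_matrix(pair: PairedDataset) -> CorrelationMatrix:
    """All-pairs Pearson correlation between miRNA and gene profiles.

    Computed by standardizing each profile across samples and taking the
    cross-product; pairs involving a constant profile come out NaN.
    """
    m = pair.mirna.values.to_numpy(dtype=float)
    g = pair.genes.values.to_numpy(dtype=float)
    n = m.shape[0]
    if n < 3:
        raise ParameterError("correlation requires at least 3 samples")

    def standardized(a: np.ndarray) -> np.ndarray:
        centered = a - a.mean(axis=0)
        norm = np.sqrt((centered**2).sum(axis=0))
        with np.errstate(invalid="ignore", divide="ignore"):
            out = centered / norm
        out[:, norm == 0] = np.nan  # constant profile -> undefined correlation
        return out

    r = standardized(m).T @ standardized(g)
    r = np.clip(r, -1.0, 1.0)
    frame = pd.DataFrame(r, index=pair.mirna.values.columns, columns=pair.genes.values.columns)
    return CorrelationMatrix(frame)


@dataclass
class TargetGeneGroups:
    """Ordered mapping miRNA id -> list of anti-correlated target gene ids."""

    groups: dict  # insertion-ordered; no empty groups stored

    def __len__(self) -> int:
        return len(self.groups)

    def __contains__(self, mirna) -> bool:
        return mirna in self.groups

    def __getitem__(self, mirna) -> list:
        return self.groups[mirna]

    @property
    def mirna_ids(self) -> list:
        return list(self.groups)

    def to_frame(self) -> pd.DataFrame:
        """Two-column table: miRNA and its comma-joined gene list."""
        return pd.DataFrame(
            {
                "miRNA": list(self.groups),
                "Targets": [", ".join(genes) for genes in self.groups.values()],
            }
        )

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_groups(
    corr: CorrelationMatrix, threshold: float = DEFAULT_CORRELATION_THRESHOLD
) -> TargetGeneGroups:
    """Form one group per miRNA: the genes with r <= threshold.

    The threshold must be strictly negative (anti-correlation is the targeting
    signal).  miRNAs with no passing gene are omitted; a gene may appear in
    several groups.  NaN correlations never pass.
    """
    if not (-1.0 < threshold < 0.0):
        raise ParameterError(f"correlation threshold must be in (-1, 0), got {threshold}")
    mask = corr.r_values.le(threshold).fillna(False)
    groups: dict = {}
    for mirna in corr.r_values.index:
        genes = corr.r_values.columns[mask.loc[mirna]].tolist()
        if genes:
            groups[mirna] = genes
    if not groups:
        raise PipelineError(f"no miRNA-mRNA associations at threshold {threshold}")
    logger.info("build_groups: %d group(s) at threshold %g", len(groups), threshold)
    return TargetGeneGroups(groups)
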