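"""Robust rank aggregation of per-iteration miRNA and gene rankings.

Every MCCV iteration yields a slightly different ranked list.  For each item
the normalized ranks across the N lists are compared with the order
statistics of N independent uniform(0,1) variables: the rho score is the
minimum over k of P(k-th smallest uniform <= observed k-th smallest
normalized rank), i.e. the upper binomial tail P(Bin(N, r_(k)) >= k), which
equals the Beta(k, N-k+1) CDF at r_(k).  A Bonferroni factor of N converts
rho into a conservative per-item p-value.  Genes inherit the rank of their
miRNA group and are aggregated the same way.
"""

from __future__ import annotations

import logging
from collections.abc import Mapping
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import ParameterError

logger = logging.getLogger(__name__)


def _rank_of(item, ranked) -> int | None:
    """Rank (1-based) of item in one list; lists may carry explicit ranks."""
    if isinstance(ranked, Mapping):
        value = ranked.get(item)
        return None if value is None else int(value)
    try:
        return ranked.index(item) + 1
    except ValueError:
        return None


def normalized_ranks(item, lists, universe_size: int) -> np.ndarray:
    """Sorted normalized ranks of one item across all lists.

    A list containing the item contributes rank/universe_size; a list without
    it contributes 1.0, the uninformative worst case (conservative treatment
    of partial lists).  Lists may be plain sequences (rank = position) or
    mappings item -> rank (used for inherited gene ranks).
    """
    lists = list(lists)
    if not lists:
        raise ParameterError("no ranked lists supplied")
    if universe_size < 1:
        raise ParameterError("universe_size must be >= 1")
    out = np.ones(len(lists))
    for i, ranked in enumerate(lists):
        rank = _rank_of(item, ranked)
        if rank is not None:
            if rank > universe_size:
                raise ParameterError(
                    f"rank {rank} exceeds universe size {universe_size} for item {item!r}"
                )
            out[i] = rank / universe_size
    out.sort()
    return out


def rho_score(sorted_norm_ranks) -> float:
    """Minimum order-statistic tail probability over all depths k.

    For sorted normalized ranks r_(1) <= ... <= r_(n), computes
    p_k = P(Bin(n, r_(k)) >= k) = Beta(k, n-k+1).cdf(r_(k)) and returns
    min_k p_k.  Small rho means the item sits improbably high across lists.
    """
    r = np.asarray(sorted_norm_ranks, dtype=float)
    if r.ndim != 1 or r.size == 0:
        raise ParameterError("expected a non-empty 1-d vector of ranks")
    if np.any((r <= 0) | (r > 1)):
        raise ParameterError("normalized ranks must lie in (0, 1]")
    if np.any(np.diff(r) < 0):
        raise ParameterError("normalized ranks must be sorted ascending")
    n = r.size
    k = np.arange(1, n + 1)
    p = stats.beta.cdf(r, k, n - k + 1)
    return float(p.min())


@dataclass
class AggregatedRanking:
    """Consensus ranking with per-item rho scores and aggregated p-values.

    ``table`` columns: item id, rho, p-value (Bonferroni-corrected rho,
    capped at 1), mean normalized rank, plus supplementary columns for
    miRNAs (target genes and group size).  Sorted ascending by p-value.
    """

    table: pd.DataFrame

    @property
    def items(self) -> list:
        return self.table.iloc[:, 0].tolist()

    def top(self, depth: int) -> pd.DataFrame:
        return self.table.head(depth)

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def aggregate(lists, universe, item_label: str = "item") -> AggregatedRanking:
    """Aggregate N ranked lists over a fixed item universe.

    p-value = min(1, rho * n_lists): a Bonferroni correction over the n
    order-statistic depths considered.  Ties are broken by smaller mean
    normalized rank, then item id; list order never matters.
    """
    lists = list(lists)
    if not lists or all(len(ranked) == 0 for ranked in lists):
        raise ParameterError("need at least one non-empty ranked list")
    universe = list(universe)
    universe_size = len(universe)
    n = len(lists)
    rows = []
    for item in universe:
        ranks = normalized_ranks(item, lists, universe_size)
        rho = rho_score(ranks)
        rows.append(
            {
                item_label: item,
                "rho": rho,
                "Score (p-value)": min(1.0, rho * n),
                "mean normalized rank": float(ranks.mean()),
            }
        )
    frame = pd.DataFrame(rows)
    frame[item_label] = frame[item_label].astype(str)
    frame = frame.sort_values(
        ["Score (p-value)", "mean normalized rank", item_label],
        kind="mergesort",
    ).reset_index(drop=True)
    return AggregatedRanking(frame)


def aggregate_mirnas(records, universe) -> AggregatedRanking:
    """Consensus miRNA ranking across iterations, with target annotations.

    Targets shown per miRNA are the union (first-appearance order) of its
    group members across iterations; #Genes is that union's size.
    """
    lists = [record.mirna_ranking for record in records]
    ranking = aggregate(lists, universe, item_label="miRNA")
    targets: dict = {m: {} for m in ranking.table["miRNA"]}
    for record in records:
        if record.groups is None:
            continue
        for mirna in record.groups.mirna_ids:
            if mirna in targets:
                for gene in record.groups[mirna]:
                    targets[mirna].setdefault(gene, None)
    table = ranking.table.copy()
    table["Targets"] = [", ".join(targets[m]) for m in table["miRNA"]]
    table["#Genes"] = [len(targets[m]) for m in table["miRNA"]]
    return AggregatedRanking(
        table[["miRNA", "Score (p-value)", "Targets", "#Genes", "rho", "mean normalized rank"]]
    )


def aggregate_genes(records, universe) -> AggregatedRanking:
    """Consensus gene ranking from the inherited-rank gene lists.

    Adds the supporting miRNA(s) whose groups carried each gene.
    """
    lists = [record.gene_ranking for record in records]
    ranking = aggregate(lists, universe, item_label="gene")
    support: dict = {g: {} for g in ranking.table["gene"]}
    for record in records:
        if record.groups is None:
            continue
        for mirna in record.groups.mirna_ids:
            for gene in record.groups[mirna]:
                if gene in support:
                    support[gene].setdefault(mirna, None)
    table = ranking.table.copy()
    table["Supporting miRNAs"] = [", ".join(support[g]) for g in table["gene"]]
    return AggregatedRanking(
        table[["gene", "Score (p-value)", "Supporting miRNAs", "rho", "mean normalized rank"]]
    )


@dataclass
class AssociationScoreTable:
    """miRNAs sorted by descending persistence score."""

    table: pd.DataFrame

    def write(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)


def association_scores(records, depth: int = 10, max_score: float = 10.0) -> AssociationScoreTable:
    """Frequency-weighted persistence of each miRNA in the top-``depth`` groups.

    Per iteration, a miRNA at rank ``rank`` <= depth contributes
    (depth - rank + 1) / depth; contributions are summed and scaled by
    max_score / n_iterations, so a miRNA ranked first in every iteration
    scores exactly ``max_score`` (default 10) regardless of iteration count.
    This score is a reconstruction of the published frequency score, whose
    exact formula is not stated; the scale is chosen to match its observed
    0-10 range.
    """
    records = list(records)
    if not records:
        raise ParameterError("need at least one iteration record")
    totals: dict = {}
    for record in records:
        for rank, mirna in enumerate(record.mirna_ranking[:depth], start=1):
            totals[mirna] = totals.get(mirna, 0.0) + (depth - rank + 1) / depth
    scale = max_score / len(records)
    frame = pd.DataFrame(
        {
            "miRNA": list(totals),
            "Score": [v * scale for v in totals.values()],
        }
    )
    frame = frame.sort_values(
        ["Score", "miRNA"], ascending=[False, True], kind="mergesort"
    ).reset_index(drop=True)
    return AssociationScoreTable(frame)
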