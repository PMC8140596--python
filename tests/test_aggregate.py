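import math

import numpy as np
import pytest

from mirgrank import (
    ParameterError,
    aggregate,
    aggregate_genes,
    association_scores,
    normalized_ranks,
    rho_score,
)
from mirgrank.mccv import IterationRecord


def binomial_tail_rho(sorted_ranks):
    """Independent oracle: explicit upper binomial-tail enumeration."""
    r = list(sorted_ranks)
    n = len(r)
    best = 1.0
    for k in range(1, n + 1):
        p = sum(
            math.comb(n, j) * r[k - 1] ** j * (1 - r[k - 1]) ** (n - j)
            for j in range(k, n + 1)
        )
        best = min(best, p)
    return best


class TestNormalizedRanks:
    def test_top_rank_everywhere(self):
        lists = [["a", "b"], ["a", "c"], ["a", "d"]]
        np.testing.assert_allclose(normalized_ranks("a", lists, 10), [0.1, 0.1, 0.1])

    def test_absence_contributes_worst_case(self):
        lists = [["b", "a", "c"], ["b", "c"]]
        np.testing.assert_allclose(normalized_ranks("a", lists, 4), [0.5, 1.0])

    def test_item_in_no_list(self):
        np.testing.assert_allclose(normalized_ranks("z", [["a"], ["b"]], 5), [1.0, 1.0])

    def test_mapping_lists_carry_explicit_ranks(self):
        lists = [{"a": 3}, {"a": 1}, {}]
        np.testing.assert_allclose(normalized_ranks("a", lists, 10), [0.1, 0.3, 1.0])

    def test_empty_collection_rejected(self):
        with pytest.raises(ParameterError):
            normalized_ranks("a", [], 5)


class TestRhoScore:
    def test_single_list(self):
        assert rho_score([0.05]) == pytest.approx(0.05)

    def test_two_list_binomial_tail(self):
        # p1 = 1 - 0.9^2 = 0.19, p2 = 0.5^2 = 0.25 -> rho = 0.19
        assert rho_score([0.1, 0.5]) == pytest.approx(0.19)

    def test_all_worst_ranks(self):
        assert rho_score([1.0, 1.0, 1.0]) == pytest.approx(1.0)

    def test_unsorted_rejected(self):
        with pytest.raises(ParameterError):
            rho_score([0.5, 0.1])

    def test_out_of_range_rejected(self):
        with pytest.raises(ParameterError):
            rho_score([0.0, 0.5])

    def test_matches_binomial_enumeration(self):
        rng = np.random.default_rng(0)
        for n in range(1, 11):
            for _ in range(20):
                ranks = np.sort(rng.uniform(1e-6, 1.0, size=n))
                assert rho_score(ranks) == pytest.approx(
                    binomial_tail_rho(ranks), abs=1e-12
                )

    def test_matches_monte_carlo_order_statistics(self):
        """rho equals the simulated minimum order-statistic tail probability."""
        rng = np.random.default_rng(1)
        draws = 100_000
        for n in (2, 5, 10):
            ranks = np.sort(rng.uniform(0.05, 0.95, size=n))
            uniforms = np.sort(rng.uniform(size=(draws, n)), axis=1)
            p_hat = (uniforms <= ranks).mean(axis=0)  # per-depth tail estimate
            k = int(np.argmin(np.abs(p_hat - p_hat.min())))
            se = math.sqrt(p_hat[k] * (1 - p_hat[k]) / draws) + 1e-9
            assert abs(rho_score(ranks) - p_hat.min()) < 3 * se + 0.003


class TestAggregate:
    def test_consistent_top_item_wins_with_tiny_pvalue(self):
        lists = [["star"] + [f"x{i}" for i in range(49)] for _ in range(100)]
        universe = ["star"] + [f"x{i}" for i in range(49)]
        ranking = aggregate(lists, universe)
        assert ranking.items[0] == "star"
        assert ranking.table.iloc[0]["Score (p-value)"] < 1e-10

    def test_permutation_invariant_to_list_order(self):
        rng = np.random.default_rng(2)
        universe = [f"i{j}" for j in range(8)]
        lists = [list(rng.permutation(universe)) for _ in range(6)]
        a = aggregate(lists, universe)
        b = aggregate(list(reversed(lists)), universe)
        assert a.items == b.items
        np.testing.assert_allclose(
            a.table["Score (p-value)"], b.table["Score (p-value)"]
        )

    def test_null_is_conservative(self):
        """Uniform random rankings: <= ~5% of items reach p < 0.05."""
        rng = np.random.default_rng(3)
        universe = [f"i{j}" for j in range(40)]
        hits = 0
        total = 0
        for _ in range(25):
            lists = [list(rng.permutation(universe)) for _ in range(10)]
            ranking = aggregate(lists, universe)
            hits += int((ranking.table["Score (p-value)"] < 0.05).sum())
            total += len(universe)
        assert hits / total <= 0.05 + 3 * math.sqrt(0.05 * 0.95 / total)

    def test_pvalues_sorted_and_in_unit_interval(self):
        rng = np.random.default_rng(4)
        universe = [f"i{j}" for j in range(10)]
        lists = [list(rng.permutation(universe)) for _ in range(5)]
        table = aggregate(lists, universe).table
        p = table["Score (p-value)"].to_numpy()
        assert (p > 0).all() and (p <= 1).all()
        assert (np.diff(p) >= 0).all()


def fake_record(index, mirna_ranking, groups_map):
    from mirgrank.grouping import TargetGeneGroups
    from mirgrank.mccv import inherited_gene_ranks
    from mirgrank.ranking import GroupScoreTable, compute_metrics

    groups = TargetGeneGroups(dict(groups_map))
    rows = [
        (m, compute_metrics(tp=4, tn=4, fp=i, fn=i), groups_map[m])
        for i, m in enumerate(mirna_ranking)
    ]
    table = GroupScoreTable(rows)
    return IterationRecord(
        index=index, seed=index, empty=False, mirna_ranking=list(mirna_ranking),
        gene_ranking=inherited_gene_ranks(table, groups), topj_results=[],
        score_table=table, groups=groups, train_sample_ids=[], test_sample_ids=[],
    )


class TestAggregateGenes:
    def test_matches_manual_aggregation_of_gene_lists(self):
        records = [
            fake_record(0, ["m1", "m2"], {"m1": ["gA"], "m2": ["gB"]}),
            fake_record(1, ["m2", "m1"], {"m1": ["gA"], "m2": ["gB"]}),
        ]
        universe = ["gA", "gB", "gC"]
        via_records = aggregate_genes(records, universe)
        manual = aggregate([r.gene_ranking for r in records], universe, item_label="gene")
        assert via_records.table["gene"].tolist() == manual.table["gene"].tolist()
        np.testing.assert_allclose(
            via_records.table["Score (p-value)"], manual.table["Score (p-value)"]
        )

    def test_always_top_gene_beats_never_grouped(self):
        records = [
            fake_record(i, ["m1"], {"m1": ["gA", "gB"]}) for i in range(5)
        ]
        ranking = aggregate_genes(records, ["gA", "gB", "gZ"])
        table = ranking.table.set_index("gene")
        assert table.loc["gA", "Score (p-value)"] < table.loc["gZ", "Score (p-value)"]
        assert table.loc["gZ", "Score (p-value)"] == 1.0


class TestAssociationScores:
    def test_always_first_reaches_scale_maximum(self):
        records = [fake_record(i, ["m1", "m2"], {"m1": ["g"], "m2": ["h"]}) for i in range(10)]
        table = association_scores(records, depth=10).table.set_index("miRNA")
        assert table.loc["m1", "Score"] == pytest.approx(10.0)
        assert table.loc["m2", "Score"] == pytest.approx(9.0)

    def test_never_in_top_depth_absent_or_zero(self):
        records = [fake_record(i, ["m1", "m2"], {"m1": ["g"], "m2": ["h"]}) for i in range(4)]
        table = association_scores(records, depth=1).table
        assert "m2" not in table["miRNA"].tolist()

    def test_scores_bounded_and_descending(self):
        rng = np.random.default_rng(5)
        mirnas = [f"m{i}" for i in range(6)]
        records = [
            fake_record(i, list(rng.permutation(mirnas)), {m: [f"g{m}"] for m in mirnas})
            for i in range(7)
        ]
        table = association_scores(records, depth=3).table
        assert (table["Score"] >= 0).all() and (table["Score"] <= 10).all()
        assert (table["Score"].diff().dropna() <= 1e-12).all()
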