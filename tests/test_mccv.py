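import numpy as np
import pytest

from mirgrank import (
    DataError,
    MccvConfig,
    ParameterError,
    iteration_seed,
    performance_summary,
    preprocess_pair,
    run_mccv,
    stratified_split,
    undersample,
)
from tests.conftest import matrix_from_arrays


def labeled_matrix(n_major, n_minor, seed=0, major="neg", minor="pos"):
    rng = np.random.default_rng(seed)
    classes = [major] * n_major + [minor] * n_minor
    return matrix_from_arrays(rng.random((n_major + n_minor, 3)), classes)


class TestUndersample:
    def test_majority_capped_at_twice_minority(self):
        matrix = labeled_matrix(405, 19)  # bladder-cancer class sizes
        out = undersample(matrix, ratio=2, seed=1)
        counts = out.class_counts()
        assert counts["neg"] == 38
        assert counts["pos"] == 19

    def test_balanced_data_unchanged(self):
        matrix = labeled_matrix(20, 20)
        out = undersample(matrix, ratio=2, seed=2)
        assert out.sample_ids == matrix.sample_ids

    def test_ratio_one_equalizes(self):
        matrix = labeled_matrix(30, 10)
        counts = undersample(matrix, ratio=1, seed=3).class_counts()
        assert counts["neg"] == 10 and counts["pos"] == 10

    def test_minority_kept_whole_and_deterministic(self):
        matrix = labeled_matrix(50, 7, seed=4)
        a = undersample(matrix, ratio=2, seed=5)
        b = undersample(matrix, ratio=2, seed=5)
        assert a.sample_ids == b.sample_ids
        assert a.class_counts()["pos"] == 7

    def test_min_rule_on_random_size_pairs(self):
        rng = np.random.default_rng(6)
        for _ in range(100):
            n_major = int(rng.integers(5, 300))
            n_minor = int(rng.integers(2, n_major + 1))
            out = undersample(labeled_matrix(n_major, n_minor), ratio=2, seed=7)
            counts = out.class_counts()
            assert counts["neg"] == min(n_major, 2 * n_minor)
            assert counts["pos"] == n_minor

    def test_ratio_below_one_rejected(self):
        with pytest.raises(ParameterError):
            undersample(labeled_matrix(10, 5), ratio=0.5)


class TestStratifiedSplit:
    def test_exact_proportionality(self):
        matrix = labeled_matrix(50, 50)
        train, test = stratified_split(matrix, 0.9, seed=0)
        assert train.class_counts().tolist() == [45, 45]
        assert test.class_counts().tolist() == [5, 5]

    def test_floor_rounding_small_class(self):
        matrix = labeled_matrix(100, 19)
        train, test = stratified_split(matrix, 0.9, seed=1)
        assert train.class_counts()["pos"] == 17  # floor(17.1)
        assert test.class_counts()["pos"] == 2

    def test_partition_contract(self):
        matrix = labeled_matrix(33, 21, seed=2)
        train, test = stratified_split(matrix, 0.8, seed=3)
        assert set(train.sample_ids).isdisjoint(test.sample_ids)
        assert sorted(train.sample_ids + test.sample_ids) == sorted(matrix.sample_ids)

    def test_both_parts_keep_each_class(self):
        matrix = labeled_matrix(4, 2)
        train, test = stratified_split(matrix, 0.95, seed=4)
        assert set(train.classes) == {"neg", "pos"}
        assert set(test.classes) == {"neg", "pos"}

    def test_too_small_class_rejected(self):
        matrix = matrix_from_arrays(np.random.default_rng(5).random((3, 2)), ["a", "a", "b"])
        with pytest.raises(DataError):
            stratified_split(matrix, 0.9, seed=5)


class TestSeedDerivation:
    def test_distinct_iterations_distinct_seeds(self):
        seeds = [iteration_seed(42, i) for i in range(100)]
        assert len(set(seeds)) == 100
        assert all(0 <= s < 2**31 for s in seeds)

    def test_stable_across_calls(self):
        assert iteration_seed(7, 3) == iteration_seed(7, 3)


@pytest.fixture(scope="module")
def mccv_run(small_planted_pair):
    pair, truth = small_planted_pair
    pair = preprocess_pair(pair)
    config = MccvConfig(n_iterations=4, master_seed=5, j_max=3)
    return pair, truth, config, run_mccv(pair, config)


class TestRunMccv:
    def test_record_count_and_distinct_splits(self, mccv_run):
        _, _, _, records = mccv_run
        assert len(records) == 4
        splits = {tuple(r.test_sample_ids) for r in records}
        assert len(splits) == 4
        assert len({r.seed for r in records}) == 4

    def test_planted_mirnas_lead_every_iteration(self, mccv_run):
        """Strong signal: a planted miRNA tops each iteration's ranking."""
        _, truth, _, records = mccv_run
        planted = set(truth.planted_mirnas)
        for record in records:
            assert planted & set(record.mirna_ranking[:3])

    def test_rankings_have_no_duplicates(self, mccv_run):
        _, _, _, records = mccv_run
        for record in records:
            assert len(record.mirna_ranking) == len(set(record.mirna_ranking))
            assert len(record.gene_ranking) == len(set(record.gene_ranking))

    def test_gene_ranks_inherited_from_mirna_rank(self, mccv_run):
        _, _, _, records = mccv_run
        for record in records:
            if record.empty:
                continue
            ranks = {m: i + 1 for i, m in enumerate(record.mirna_ranking)}
            for gene, rank in record.gene_ranking.items():
                carriers = [
                    ranks[m] for m in record.groups.mirna_ids if gene in record.groups[m]
                ]
                assert rank == min(carriers)  # best rank wins

    def test_train_test_disjoint(self, mccv_run):
        _, _, _, records = mccv_run
        for record in records:
            assert set(record.train_sample_ids).isdisjoint(record.test_sample_ids)

    def test_undersample_invariant_inside_run(self, mccv_run):
        pair, _, config, records = mccv_run
        labels = pair.classes
        for record in records:
            used = labels.loc[record.train_sample_ids + record.test_sample_ids]
            counts = used.value_counts()
            assert counts.max() <= config.undersample_ratio * counts.min()

    def test_reproducible_bitwise(self, mccv_run):
        pair, _, config, records = mccv_run
        again = run_mccv(pair, config)
        for a, b in zip(records, again):
            assert a.mirna_ranking == b.mirna_ranking
            assert a.gene_ranking == b.gene_ranking
            assert a.test_sample_ids == b.test_sample_ids
            assert [r.auc for r in a.topj_results] == [r.auc for r in b.topj_results]

    def test_performance_summary_mean_sd(self, mccv_run):
        _, _, _, records = mccv_run
        summary = performance_summary(records)
        assert "Accuracy (mean)" in summary.columns
        assert "AUC (std)" in summary.columns
        assert summary["j"].tolist() == sorted(summary["j"].tolist())
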