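import numpy as np
import pytest
from hypothesis import given, strategies as st

import ctbench
from ctbench import (
    ClusterMedianProfile,
    binary_scores,
    cv_per_gene,
    select_bin_top_fraction,
    select_cv_threshold,
    subset_matrix,
)
from ctbench.features import BinaryScoreTable


def profile_from_rows(rows):
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    g, n = rows.shape
    return ClusterMedianProfile(
        gene_ids=[f"g{i}" for i in range(g)],
        cluster_names=[f"k{i}" for i in range(n)],
        medians=rows,
    )


def brute_force_binary_score(y, x):
    """Scalar reference implementation of the binary expression score."""
    n = len(y)
    if y[x] == 0:
        return 0.0
    total = 0.0
    for i in range(n):
        total += max(0.0, 1.0 - y[i] / y[x])
    return total / (n - 1)


class TestBinaryScore:
    @pytest.mark.parametrize(
        "row,target,expected",
        [
            ((4, 0, 0), 0, 1.0),
            ((4, 2, 0), 0, 0.75),
            ((2, 4, 0), 0, 0.5),   # the (1 - 4/2) term clips to 0
            ((0, 4, 0), 0, 0.0),   # silent in the target cluster
        ],
    )
    def test_worked_examples(self, row, target, expected):
        table = binary_scores(profile_from_rows([row]))
        assert table.scores[0, target] == pytest.approx(expected, abs=1e-12)

    def test_two_cluster_minimum(self):
        with pytest.raises(ValueError):
            binary_scores(profile_from_rows(np.ones((2, 1))))

    @given(
        st.lists(st.floats(0, 10, allow_nan=False), min_size=2, max_size=8),
        st.data(),
    )
    def test_matches_brute_force_and_stays_in_range(self, row, data):
        x = data.draw(st.integers(0, len(row) - 1))
        table = binary_scores(profile_from_rows([row]))
        expected = brute_force_binary_score(row, x)
        assert table.scores[0, x] == pytest.approx(expected, abs=1e-12)
        assert 0.0 <= table.scores[0, x] <= 1.0
        # score 1 exactly when the gene's median is positive only in cluster x
        exclusive = row[x] > 0 and all(v == 0 for i, v in enumerate(row) if i != x)
        assert (table.scores[0, x] == 1.0) == exclusive

    @given(
        st.lists(st.floats(0.1, 10, allow_nan=False), min_size=3, max_size=6),
        st.data(),
    )
    def test_monotone_in_off_target_medians(self, row, data):
        x = data.draw(st.integers(0, len(row) - 1))
        j = data.draw(st.integers(0, len(row) - 1).filter(lambda v: v != x))
        lowered = list(row)
        lowered[j] = lowered[j] * data.draw(st.floats(0, 1, exclude_max=True))
        before = binary_scores(profile_from_rows([row])).scores[0, x]
        after = binary_scores(profile_from_rows([lowered])).scores[0, x]
        assert after >= before - 1e-12


class TestBinSelection:
    def test_union_of_overlapping_top_lists(self):
        rng = np.random.default_rng(0)
        g = 100
        scores = rng.uniform(0, 0.5, size=(g, 2))
        # plant top-5 lists sharing exactly 2 genes
        scores[:5, 0] = [0.99, 0.98, 0.97, 0.96, 0.95]
        scores[3:8, 1] = [0.99, 0.98, 0.97, 0.96, 0.95]
        table = BinaryScoreTable(
            gene_ids=np.asarray([f"g{i:03d}" for i in range(g)], dtype=object),
            cluster_names=np.asarray(["a", "b"], dtype=object),
            scores=scores,
        )
        assert len(select_bin_top_fraction(table, 0.05)) == 8

    def test_full_fraction_selects_everything(self):
        table = binary_scores(profile_from_rows(np.random.default_rng(1).uniform(0, 5, (30, 3))))
        assert len(select_bin_top_fraction(table, 1.0)) == 30

    def test_one_percent_of_100_genes_is_one_per_cluster(self):
        rng = np.random.default_rng(2)
        scores = rng.uniform(0, 0.5, size=(100, 3))
        scores[10, 0] = scores[20, 1] = scores[30, 2] = 0.9  # disjoint winners
        table = BinaryScoreTable(
            gene_ids=np.asarray([f"g{i:03d}" for i in range(100)], dtype=object),
            cluster_names=np.asarray(["a", "b", "c"], dtype=object),
            scores=scores,
        )
        assert sorted(select_bin_top_fraction(table, 0.01).gene_ids) == ["g010", "g020", "g030"]

    def test_invalid_fraction(self):
        table = binary_scores(profile_from_rows([[1, 0]]))
        for bad in (0.0, 1.5, -0.1):
            with pytest.raises(ValueError):
                select_bin_top_fraction(table, bad)

    def test_nesting_on_random_tables(self):
        rng = np.random.default_rng(3)
        table = binary_scores(profile_from_rows(rng.uniform(0, 5, (200, 4))))
        sets = {f: set(select_bin_top_fraction(table, f).gene_ids) for f in (0.01, 0.05, 0.10, 0.15)}
        assert sets[0.01] <= sets[0.05] <= sets[0.10] <= sets[0.15]


class TestCv:
    def test_worked_examples(self):
        profile = profile_from_rows([[3, 3, 3, 3], [0, 0, 0, 4], [1, 3]][0:1])
        assert cv_per_gene(profile).cv[0] == pytest.approx(0.0)
        assert cv_per_gene(profile_from_rows([[0, 0, 0, 4]])).cv[0] == pytest.approx(np.sqrt(3), abs=1e-4)
        assert cv_per_gene(profile_from_rows([[1, 3]])).cv[0] == pytest.approx(0.5)

    def test_sample_mode_uses_ddof_one(self):
        table = cv_per_gene(profile_from_rows([[1, 3]]), ddof_mode="sample")
        assert table.cv[0] == pytest.approx(np.sqrt(2) / 2)
        assert table.ddof_mode == "sample"

    def test_zero_mean_row_rejected(self):
        with pytest.raises(ValueError, match="zero-mean"):
            cv_per_gene(profile_from_rows([[0, 0, 0]]))

    def test_threshold_selection(self):
        profile = profile_from_rows(np.diag([1.0, 2.0, 3.0]) + 0.0)
        cv = cv_per_gene(profile)
        cv.cv = np.array([0.4, 2.6, 3.5])
        assert list(select_cv_threshold(cv, 2.5).gene_ids) == ["g1", "g2"]
        assert len(select_cv_threshold(cv, 0.0)) == 3
        with pytest.warns(UserWarning, match="empty"):
            assert len(select_cv_threshold(cv, 99.0)) == 0

    def test_threshold_nesting(self, small_filtered):
        _, profile = small_filtered
        cv = cv_per_gene(profile)
        sets = {t: set(select_cv_threshold(cv, t).gene_ids) for t in (0.52, 1.5, 2.5, 3.5, 4.5)}
        assert sets[4.5] <= sets[3.5] <= sets[2.5] <= sets[1.5] <= sets[0.52]


class TestSubsetMatrix:
    def test_restricts_in_feature_order(self, small_filtered):
        filtered, _ = small_filtered
        features = ctbench.FeatureSet(gene_ids=filtered.gene_ids[[2, 0]])
        out = subset_matrix(filtered, features)
        assert list(out.gene_ids) == list(filtered.gene_ids[[2, 0]])
        np.testing.assert_allclose(out.dense_values(), filtered.dense_values()[[2, 0]])

    def test_identity_subset(self, small_filtered):
        filtered, _ = small_filtered
        out = subset_matrix(filtered, ctbench.FeatureSet(gene_ids=filtered.gene_ids))
        np.testing.assert_allclose(out.dense_values(), filtered.dense_values())

    def test_unknown_gene_named_in_error(self, small_filtered):
        filtered, _ = small_filtered
        with pytest.raises(KeyError, match="NOPE"):
            subset_matrix(filtered, ctbench.FeatureSet(gene_ids=["NOPE"]))


class TestMarkerRecovery:
    def test_planted_markers_score_one(self, small_synth, small_filtered):
        _, _, truth = small_synth
        _, profile = small_filtered
        table = binary_scores(profile)
        cluster_index = {name: i for i, name in enumerate(table.cluster_names)}
        gene_index = {g: i for i, g in enumerate(table.gene_ids)}
        for marker, home in truth.marker_cluster.items():
            assert table.scores[gene_index[marker], cluster_index[home]] == pytest.approx(1.0)

    def test_planted_markers_enter_one_percent_bin_set(self):
        # one marker per cluster, so a single top-ranked gene per cluster
        # (the 1% cutoff on this genome) must be the planted marker
        spec = ctbench.SyntheticSpec(
            n_clusters=4, cluster_sizes=[24, 32, 40, 48], markers_per_cluster=1,
            n_graded_genes=10, n_sparse_genes=60, n_baseline_genes=30,
            nb_mean_low=5.0, dropout_rate=0.1, seed=21,
        )
        matrix, truth = ctbench.generate(spec)
        _, profile = ctbench.preprocess_counts(matrix)
        bin_set = set(select_bin_top_fraction(binary_scores(profile), 0.01).gene_ids)
        assert set(truth.marker_cluster) <= bin_set

    def test_marker_cv_exceeds_bulk_of_graded_cv(self, small_synth, small_filtered):
        _, _, truth = small_synth
        _, profile = small_filtered
        cv = cv_per_gene(profile)
        by_gene = dict(zip(cv.gene_ids, cv.cv))
        marker_cv = [by_gene[g] for g in truth.genes_with_role("marker")]
        graded_cv = [by_gene[g] for g in truth.genes_with_role("graded") if g in by_gene]
        assert min(marker_cv) > np.percentile(graded_cv, 95)
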