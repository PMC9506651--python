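import itertools

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import rankdata

import ctbench
from ctbench import (
    ClassifierSpec,
    PredictionSet,
    confusion,
    f_beta_score,
    median_f_beta,
    overfitting_report,
    per_cluster_metrics,
    train,
    wilcoxon_signed_rank,
)


def prediction_set(true, pred, classes=None):
    true = np.asarray(list(true), dtype=object)
    pred = np.asarray(list(pred), dtype=object)
    if classes is None:
        classes = sorted(set(true) | set(pred))
    return PredictionSet(
        cell_ids=np.asarray([f"c{i}" for i in range(len(true))], dtype=object),
        true_labels=true,
        predicted_labels=pred,
        class_names=np.asarray(classes, dtype=object),
    )


WORKED = prediction_set("AAABBC", "AABBBC")


class TestConfusion:
    def test_direct_tally(self):
        cm = confusion(WORKED)
        frame = cm.to_frame()
        assert frame.loc["A", "A"] == 2 and frame.loc["A", "B"] == 1
        assert frame.loc["B", "B"] == 2 and frame.loc["C", "C"] == 1
        assert frame.to_numpy().sum() == 6

    def test_perfect_predictions_are_diagonal(self):
        cm = confusion(prediction_set("ABC", "ABC"))
        assert (cm.counts == np.eye(3)).all()

    def test_single_cell(self):
        cm = confusion(prediction_set("A", "A", classes=["A", "B"]))
        assert cm.counts.sum() == 1 and cm.counts[0, 0] == 1

    def test_label_outside_classes_rejected(self):
        with pytest.raises(ValueError, match="outside"):
            confusion(prediction_set("AB", "AZ", classes=["A", "B"]))


class TestPerClusterMetrics:
    def test_worked_f_half_values(self):
        metrics = per_cluster_metrics(confusion(WORKED), beta=0.5).table
        assert metrics.loc["A", "precision"] == pytest.approx(1.0)
        assert metrics.loc["A", "recall"] == pytest.approx(2 / 3)
        assert metrics.loc["A", "f_beta"] == pytest.approx(0.9091, abs=1e-4)
        assert metrics.loc["B", "f_beta"] == pytest.approx(0.7143, abs=1e-4)
        assert metrics.loc["C", "f_beta"] == pytest.approx(1.0)
        assert list(metrics["support"]) == [3, 2, 1]

    def test_equal_precision_recall_identity(self):
        for beta in (0.25, 0.5, 1.0, 2.0):
            assert f_beta_score(2 / 3, 2 / 3, beta) == pytest.approx(2 / 3)

    def test_zero_denominator_conventions(self):
        assert f_beta_score(0.0, 0.0, 0.5) == 0.0
        metrics = per_cluster_metrics(confusion(prediction_set("AB", "AA")), beta=0.5).table
        assert metrics.loc["B", "precision"] == 0.0  # B never predicted... and never right
        assert metrics.loc["B", "f_beta"] == 0.0

    def test_matches_sklearn_fbeta(self):
        from sklearn.metrics import fbeta_score as sk_fbeta

        rng = np.random.default_rng(0)
        true = rng.choice(list("ABCD"), size=200)
        pred = rng.choice(list("ABCD"), size=200)
        ours = per_cluster_metrics(confusion(prediction_set(true, pred)), beta=0.5).table
        theirs = sk_fbeta(true, pred, beta=0.5, labels=list("ABCD"), average=None, zero_division=0)
        np.testing.assert_allclose(ours["f_beta"].to_numpy(), theirs, atol=1e-12)

    def test_f_beta_monotone_and_limits(self):
        grid = np.linspace(0.05, 1.0, 12)
        for p, r in itertools.product(grid, grid):
            assert f_beta_score(p + 1e-3, r, 0.5) > f_beta_score(p, r, 0.5)
            assert f_beta_score(p, r + 1e-3, 0.5) > f_beta_score(p, r, 0.5)
            # F1 is the harmonic mean of precision and recall
            assert f_beta_score(p, r, 1.0) == pytest.approx(2 * p * r / (p + r))
            # beta -> 0 recovers precision
            assert f_beta_score(p, r, 1e-3) == pytest.approx(p, abs=1e-3)

    def test_micro_consistency(self):
        rng = np.random.default_rng(1)
        true = rng.choice(list("ABC"), size=100)
        pred = rng.choice(list("ABC"), size=100)
        cm = confusion(prediction_set(true, pred))
        assert np.diag(cm.counts).sum() == (true == pred).sum()
        assert per_cluster_metrics(cm).table["support"].sum() == 100


class TestMedianFBeta:
    def test_examples(self):
        metrics = per_cluster_metrics(confusion(WORKED), beta=0.5)
        assert median_f_beta(metrics) == pytest.approx(0.9091, abs=1e-4)
        perfect = per_cluster_metrics(confusion(prediction_set("ABC", "ABC")))
        assert median_f_beta(perfect) == 1.0
        two = per_cluster_metrics(confusion(prediction_set("AB", "AB")))
        two.table.loc["A", "f_beta"], two.table.loc["B", "f_beta"] = 0.4, 0.8
        assert median_f_beta(two) == pytest.approx(0.6)


def enumeration_oracle(diffs):
    """Literal 2^n sign-vector enumeration of the two-sided exact p-value."""
    diffs = np.asarray(diffs, dtype=float)
    diffs = diffs[diffs != 0]
    n = len(diffs)
    ranks = rankdata(np.abs(diffs))
    w_obs = min(ranks[diffs > 0].sum(), ranks[diffs < 0].sum())
    count = sum(
        1
        for signs in itertools.product((0, 1), repeat=n)
        if sum(r for s, r in zip(signs, ranks) if s) <= w_obs + 1e-9
    )
    return min(1.0, 2.0 * count / 2**n)


class TestWilcoxon:
    def test_worked_examples(self):
        res = wilcoxon_signed_rank([1, 2, 3], [0, 0, 0])
        assert res.statistic == 0 and res.p_value == pytest.approx(0.25)
        assert res.method == "exact" and res.n_effective == 3
        res = wilcoxon_signed_rank([5, -5], [0, 0])
        assert res.statistic == pytest.approx(1.5)
        assert res.p_value == pytest.approx(1.0)

    def test_identical_vectors_are_degenerate(self):
        res = wilcoxon_signed_rank([1.0, 2.0], [1.0, 2.0])
        assert res.degenerate and res.p_value is None and res.n_effective == 0

    @given(st.lists(st.integers(-5, 5), min_size=1, max_size=10))
    def test_exact_path_matches_enumeration(self, diffs):
        if all(d == 0 for d in diffs):
            return
        res = wilcoxon_signed_rank(np.asarray(diffs, dtype=float), np.zeros(len(diffs)))
        assert res.method == "exact"
        assert res.p_value == pytest.approx(enumeration_oracle(diffs), abs=1e-12)

    def test_tie_free_exact_matches_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(2)
        for _ in range(20):
            d = rng.permutation(np.arange(1, 13)) * rng.choice([-1, 1], size=12)
            ours = wilcoxon_signed_rank(d.astype(float), np.zeros(12))
            theirs = scipy_wilcoxon(d, mode="exact")
            assert ours.p_value == pytest.approx(theirs.pvalue, abs=1e-12)

    def test_large_n_normal_approximation_matches_scipy(self):
        from scipy.stats import wilcoxon as scipy_wilcoxon

        rng = np.random.default_rng(3)
        d = rng.normal(0.3, 1.0, size=40)
        ours = wilcoxon_signed_rank(d, np.zeros(40))
        assert ours.method == "normal_approximation"
        theirs = scipy_wilcoxon(d, mode="approx", correction=True)
        assert ours.p_value == pytest.approx(theirs.pvalue, rel=1e-6)


class TestOverfittingReport:
    def test_overparameterized_model_trains_better_than_it_validates(self):
        spec = ctbench.SyntheticSpec(
            n_clusters=3, cluster_sizes=[20, 24, 28], markers_per_cluster=1,
            n_graded_genes=40, n_sparse_genes=10, n_baseline_genes=5,
            nb_mean_high=8.0, dropout_rate=0.4, seed=13,
        )
        matrix, _ = ctbench.generate(spec)
        filtered, _ = ctbench.preprocess_counts(matrix)
        split = ctbench.stratified_split(filtered.labels, cell_ids=filtered.cell_ids, seed=13)
        model = train(
            ClassifierSpec(family="random_forest", hyperparameters={"n_estimators": 200}, seed=13),
            ctbench.split_matrix(filtered, split, "train"),
        )
        report = overfitting_report(model, filtered, split)
        medians = report.medians()
        assert medians["train"] >= medians["validation"]
        assert set(report.comparisons) == {("train", "validation"), ("validation", "test")}
        assert "median F-beta" in report.summary()

    def test_constant_predictor_scores_zero_elsewhere(self):
        preds = prediction_set("ABCABC", "AAAAAA")
        metrics = per_cluster_metrics(confusion(preds)).table
        assert metrics.loc["B", "f_beta"] == 0.0 and metrics.loc["C", "f_beta"] == 0.0

    def test_cell_universe_mismatch_rejected(self, separable_matrix):
        split = ctbench.stratified_split(
            separable_matrix.labels, cell_ids=separable_matrix.cell_ids, seed=0
        )
        model = train(ClassifierSpec(family="logistic_regression"), separable_matrix)
        shrunk = separable_matrix.subset_cells(np.arange(separable_matrix.n_cells) < 50)
        with pytest.raises(ValueError, match="mismatch"):
            overfitting_report(model, shrunk, split)


def test_f_beta_box_plot_smoke(tmp_path):
    import matplotlib

    matplotlib.use("Agg")
    metrics = per_cluster_metrics(confusion(WORKED))
    ax = ctbench.evaluate.plot_f_beta_distributions({"test": metrics})
    assert ax.get_ylabel().startswith("per-cluster F-beta")
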