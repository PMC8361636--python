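import itertools
import math

import numpy as np
import pandas as pd
import pytest

from priorfs.datasets import ExpressionDataset
from priorfs.evaluation import (
    DEFAULT_CLASSIFIERS,
    MetricsTable,
    annotation_overlap,
    cross_dataset_validation,
    enrich,
    feature_overlap,
    kendalls_w,
    kfold_cv,
    runtime_profile,
    sweep_feature_sizes,
)
from priorfs.selection import FeatureRanking


def _separable_ds(n_per_class=15, n_genes=5, effect=10.0, seed=0):
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n_genes, n))
    X[:, :n_per_class] += effect  # every gene separates the classes
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i:02d}" for i in range(n)]
    labels = pd.Series(["a"] * n_per_class + ["b"] * n_per_class, index=samples)
    return ExpressionDataset(pd.DataFrame(X, index=genes, columns=samples), labels)


def _shuffled_ds(n_per_class=20, n_genes=5, seed=0):
    """Balanced labels independent of the data: chance-level problem."""
    rng = np.random.default_rng(seed)
    n = 2 * n_per_class
    X = rng.standard_normal((n_genes, n))
    genes = [f"g{i}" for i in range(n_genes)]
    samples = [f"s{i:02d}" for i in range(n)]
    labels = pd.Series(
        rng.permutation(["a"] * n_per_class + ["b"] * n_per_class), index=samples
    )
    return ExpressionDataset(pd.DataFrame(X, index=genes, columns=samples), labels)


class TestKfoldCV:
    def test_separable_classes_score_one_for_every_classifier(self):
        ds = _separable_ds()
        table = kfold_cv(ds, ds.gene_ids, DEFAULT_CLASSIFIERS, k=5, seed=0)
        acc = table.records[table.records["metric_name"] == "accuracy"]
        per_clf = acc.groupby("classifier")["value"].mean()
        assert set(per_clf.index) == set(DEFAULT_CLASSIFIERS)
        assert (per_clf == 1.0).all()

    def test_same_seed_is_bit_identical(self):
        ds = _separable_ds(effect=1.0)
        a = kfold_cv(ds, ds.gene_ids, ["random_forest"], k=5, seed=3)
        b = kfold_cv(ds, ds.gene_ids, ["random_forest"], k=5, seed=3)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_fold_indices_cover_range_once_per_cell(self):
        ds = _separable_ds()
        table = kfold_cv(ds, ds.gene_ids, ["knn3"], k=5, seed=0)
        folds = table.records[table.records["metric_name"] == "accuracy"]["fold"]
        assert sorted(folds) == list(range(5))

    def test_stratification_balances_folds(self):
        # 24 a / 12 b, k=6: every fold must hold 4 a and 2 b exactly
        from sklearn.model_selection import StratifiedKFold

        y = np.array(["a"] * 24 + ["b"] * 12)
        skf = StratifiedKFold(n_splits=6, shuffle=True, random_state=1)
        global_frac = (y == "a").mean()
        for _, test in skf.split(np.zeros((36, 1)), y):
            fold_frac = (y[test] == "a").mean()
            assert abs(fold_frac - global_frac) * len(test) < 1.0

    def test_class_smaller_than_k_rejected(self):
        ds = _separable_ds(n_per_class=3)
        with pytest.raises(ValueError, match="fewer than k"):
            kfold_cv(ds, ds.gene_ids, ["knn3"], k=5, seed=0)

    def test_unknown_classifier_rejected(self):
        ds = _separable_ds()
        with pytest.raises(ValueError, match="unknown classifier"):
            kfold_cv(ds, ds.gene_ids, ["perceptron9000"], k=5, seed=0)

    def test_no_training_leakage_matches_train_only_oracle(self):
        """A constant-in-train, extreme-in-test canary must not move the fit.

        The oracle fits imputation and scaling on the training fold only, by
        hand; a leaky implementation (statistics over all samples) provably
        differs on this fixture, so fold-wise equality with the oracle rules
        leakage out.
        """
        from sklearn.model_selection import StratifiedKFold
        from sklearn.naive_bayes import GaussianNB

        ds = _separable_ds(n_per_class=10, n_genes=3, effect=2.0, seed=4)
        vals = ds.values.copy()
        vals.loc["canary"] = 0.0
        vals.loc["canary", "s00"] = 1e6  # extreme in exactly one sample
        ds = ExpressionDataset(vals, ds.labels)

        table = kfold_cv(ds, ds.gene_ids, ["naive_bayes"], k=5, seed=2)
        got = (
            table.records[table.records["metric_name"] == "accuracy"]
            .set_index("fold")["value"]
        )

        order = np.argsort(np.asarray(ds.sample_ids))
        X = ds.values.T.to_numpy()[order]
        y = ds.labels.to_numpy()[order]
        skf = StratifiedKFold(n_splits=5, shuffle=True, random_state=2)
        leak_detected = False
        for fold, (train, test) in enumerate(skf.split(X, y)):
            mu, sd = X[train].mean(axis=0), X[train].std(axis=0)
            sd = np.where(sd == 0, 1.0, sd)
            clf = GaussianNB().fit((X[train] - mu) / sd, y[train])
            acc = (clf.predict((X[test] - mu) / sd) == y[test]).mean()
            assert got.loc[fold] == pytest.approx(acc)
            # show the canary has teeth: full-data statistics differ
            if not np.allclose(mu, X.mean(axis=0)):
                leak_detected = True
        assert leak_detected


class TestSweepAndCrossDataset:
    def test_full_size_sweep_equals_plain_cv(self):
        ds = _separable_ds()
        ranking = FeatureRanking.from_scores(
            {g: float(i) for i, g in enumerate(ds.gene_ids)}, "m"
        )
        sweep = sweep_feature_sizes(ranking, ds, ["knn3"], 5, [len(ranking)], seed=1)
        direct = kfold_cv(ds, ranking.gene_ids, ["knn3"], 5, seed=1, selector_name="m")
        pd.testing.assert_frame_equal(
            sweep.records.reset_index(drop=True), direct.records
        )

    def test_noiseless_informative_genes_accuracy_non_decreasing(self):
        n = 30
        samples = [f"s{i:02d}" for i in range(n)]
        labels = pd.Series(["a"] * 15 + ["b"] * 15, index=samples)
        X = np.tile((labels == "a").to_numpy(dtype=float) * 4.0, (3, 1))
        X += np.array([[0.0], [0.1], [0.2]])  # distinct but noiseless rows
        ds = ExpressionDataset(
            pd.DataFrame(X, index=["g0", "g1", "g2"], columns=samples), labels
        )
        ranking = FeatureRanking.from_scores({"g0": 3.0, "g1": 2.0, "g2": 1.0}, "m")
        table = sweep_feature_sizes(ranking, ds, ["knn3"], 5, [1, 2, 3], seed=0)
        acc = (
            table.records[table.records["metric_name"] == "accuracy"]
            .groupby("feature_set_size")["value"].mean()
        )
        assert (acc.diff().dropna() >= 0).all()

    def test_row_counts(self):
        ds = _separable_ds()
        ranking = FeatureRanking.from_scores(
            {g: float(i) for i, g in enumerate(ds.gene_ids)}, "m"
        )
        table = sweep_feature_sizes(ranking, ds, ["knn3", "svm"], 5, [1, 2, 3], seed=0)
        acc = table.records[table.records["metric_name"] == "accuracy"]
        assert len(acc) == 3 * 2 * 5

    def test_cross_dataset_identity_equals_in_dataset(self):
        ds = _separable_ds()
        direct = kfold_cv(ds, ds.gene_ids, ["knn3"], 5, seed=7, selector_name="x")
        cross = cross_dataset_validation(
            ds.gene_ids, ds, ["knn3"], 5, seed=7, selector_name="x"
        )
        pd.testing.assert_frame_equal(cross.records, direct.records)

    def test_cross_dataset_invariant_to_sample_order(self):
        ds = _separable_ds()
        rng = np.random.default_rng(0)
        perm = rng.permutation(ds.sample_ids)
        ds_perm = ExpressionDataset(ds.values[perm], ds.labels.loc[perm])
        a = cross_dataset_validation(ds.gene_ids, ds, ["knn3"], 5, seed=1)
        b = cross_dataset_validation(ds.gene_ids, ds_perm, ["knn3"], 5, seed=1)
        pd.testing.assert_frame_equal(a.records, b.records)

    def test_missing_features_dropped_not_fatal(self):
        ds = _separable_ds()
        table = cross_dataset_validation(
            ds.gene_ids + ["absent1", "absent2"], ds, ["knn3"], 5, seed=0
        )
        assert not table.records.empty

    def test_empty_intersection_errors(self):
        ds = _separable_ds()
        with pytest.raises(ValueError, match="no selected feature"):
            cross_dataset_validation(["nope"], ds, ["knn3"], 5, seed=0)


def naive_kendalls_w(orderings):
    """Textbook Kendall's W for tie-free orderings: no shared code paths."""
    items = sorted(orderings[0])
    m, n = len(orderings), len(items)
    rank_sums = {
        item: sum(order.index(item) + 1 for order in orderings) for item in items
    }
    mean_r = m * (n + 1) / 2
    s = sum((rank_sums[i] - mean_r) ** 2 for i in items)
    return 12 * s / (m**2 * (n**3 - n))


class TestKendallsW:
    def test_identical_rankings_give_one(self):
        order = ["a", "b", "c", "d"]
        assert kendalls_w([order] * 4) == pytest.approx(1.0)

    def test_reversed_pair_gives_zero(self):
        assert kendalls_w([["a", "b", "c"], ["c", "b", "a"]]) == pytest.approx(0.0)

    def test_matches_naive_oracle_on_random_panels(self):
        rng = np.random.default_rng(17)
        for _ in range(200):
            m = int(rng.integers(2, 6))
            n = int(rng.integers(2, 9))
            items = [f"i{j}" for j in range(n)]
            panel = [list(rng.permutation(items)) for _ in range(m)]
            assert kendalls_w(panel) == pytest.approx(naive_kendalls_w(panel))

    def test_invariant_under_item_relabeling(self):
        rng = np.random.default_rng(4)
        items = [f"i{j}" for j in range(6)]
        panel = [list(rng.permutation(items)) for _ in range(3)]
        relabel = {i: f"X{i}" for i in items}
        renamed = [[relabel[i] for i in order] for order in panel]
        assert kendalls_w(panel) == pytest.approx(kendalls_w(renamed))

    def test_mismatched_item_sets_rejected(self):
        with pytest.raises(ValueError, match="identical item sets"):
            kendalls_w([["a", "b"], ["a", "c"]])

    def test_tied_scores_use_average_ranks(self):
        # two rankings agreeing except one has a full tie: W must stay in [0,1]
        r1 = FeatureRanking.from_scores({"a": 3.0, "b": 2.0, "c": 1.0}, "x")
        r2 = FeatureRanking.from_scores({"a": 1.0, "b": 1.0, "c": 1.0}, "y")
        w = kendalls_w([r1, r2])
        assert 0.0 <= w <= 1.0


class TestOverlaps:
    def test_disjoint_sets(self):
        s = feature_overlap({"A": {"x", "y", "z"}, "B": {"u", "v", "w"}})
        assert s.counts[frozenset({"A"})] == 3
        assert s.counts[frozenset({"B"})] == 3
        assert s.counts[frozenset({"A", "B"})] == 0

    def test_identical_sets_fill_only_full_cell(self):
        s = feature_overlap({"A": {"x", "y"}, "B": {"x", "y"}, "C": {"x", "y"}})
        assert s.counts[frozenset({"A", "B", "C"})] == 2
        assert all(
            c == 0 for key, c in s.counts.items() if key != frozenset({"A", "B", "C"})
        )

    def test_exclusive_counts_sum_to_union(self):
        rng = np.random.default_rng(8)
        universe = [f"g{i}" for i in range(40)]
        for _ in range(25):
            sets = {
                name: set(rng.choice(universe, rng.integers(0, 20), replace=False))
                for name in ("A", "B", "C")
            }
            s = feature_overlap(sets)
            assert s.total() == len(set().union(*sets.values()))
            # element-wise membership oracle
            for key, count in s.counts.items():
                expected = sum(
                    1
                    for g in universe
                    if {n for n in sets if g in sets[n]} == set(key)
                )
                assert count == expected

    def test_annotation_overlap_allows_empty_set(self):
        s = annotation_overlap({"A": set(), "B": {"t1", "t2"}})
        assert s.counts[frozenset({"A"})] == 0
        assert s.counts[frozenset({"A", "B"})] == 0
        assert s.counts[frozenset({"B"})] == 2

    def test_single_set_rejected(self):
        with pytest.raises(ValueError):
            feature_overlap({"A": {"x"}})


def hypergeom_tail_oracle(overlap, N, K, n):
    """Exact upper-tail sum with math.comb only."""
    total = 0.0
    for j in range(overlap, min(K, n) + 1):
        total += math.comb(K, j) * math.comb(N - K, n - j)
    return total / math.comb(N, n)


class TestEnrichment:
    @pytest.fixture
    def universe(self):
        background = {f"g{i:04d}" for i in range(1000)}
        library = {
            "term_hit": sorted(background)[:20],
            "term_other": sorted(background)[500:540],
        }
        return background, library

    def test_exact_term_match_ranks_first(self, universe):
        background, library = universe
        query = set(library["term_hit"])
        hits = enrich(query, library, background)
        assert hits and hits[0].term == "term_hit"
        assert hits[0].adjusted_p < 0.05
        assert hits[0].overlap_count == 20

    def test_query_in_no_term_is_empty(self, universe):
        background, library = universe
        query = set(sorted(background)[900:910])
        assert enrich(query, library, background) == []

    def test_fisher_p_matches_tail_sum_oracle(self):
        # the printed 2x2: overlap 5, query-only 5, term-only 5, rest 985
        background = {f"g{i}" for i in range(1000)}
        genes = sorted(background)
        query = set(genes[:10])
        library = {"t": genes[5:15]}
        hits = enrich(query, library, background, alpha=1.0)
        expected = hypergeom_tail_oracle(5, 1000, 10, 10)
        assert hits[0].p_value == pytest.approx(expected, rel=1e-9)

    def test_fisher_p_matches_oracle_on_random_tables(self):
        from scipy.stats import hypergeom

        rng = np.random.default_rng(23)
        for _ in range(50):
            N = int(rng.integers(20, 500))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            assert hypergeom.sf(k - 1, N, K, n) == pytest.approx(
                hypergeom_tail_oracle(k, N, K, n), rel=1e-9, abs=1e-12
            )

    def test_p_monotone_decreasing_in_overlap(self):
        background = {f"g{i}" for i in range(200)}
        genes = sorted(background)
        prev = 1.1
        for overlap in (2, 4, 6, 8, 10):
            query = set(genes[:10])
            library = {"t": genes[10 - overlap : 30 - overlap]}
            hits = enrich(query, library, background, alpha=1.0)
            assert hits[0].overlap_count == overlap
            assert hits[0].p_value < prev
            prev = hits[0].p_value

    def test_invariant_to_gene_relabeling(self, universe):
        background, library = universe
        query = set(library["term_hit"][:10]) | set(sorted(background)[800:810])
        before = enrich(query, library, background, alpha=1.0)
        rename = {g: f"R{g}" for g in background}
        after = enrich(
            {rename[g] for g in query},
            {t: [rename[g] for g in gs] for t, gs in library.items()},
            {rename[g] for g in background},
            alpha=1.0,
        )
        assert [(h.term, h.overlap_count, h.p_value) for h in before] == [
            (h.term, h.overlap_count, h.p_value) for h in after
        ]

    def test_adjusted_p_not_below_raw(self, universe):
        background, library = universe
        query = set(library["term_hit"][:10])
        for h in enrich(query, library, background, alpha=1.0):
            assert h.adjusted_p >= h.p_value - 1e-12

    def test_empty_query_rejected(self, universe):
        background, library = universe
        with pytest.raises(ValueError):
            enrich(set(), library, background)


def test_runtime_profile_returns_result_and_nonnegative_seconds():
    result, seconds = runtime_profile(lambda: 42)
    assert result == 42
    assert seconds >= 0.0


def test_metrics_table_rejects_out_of_range_accuracy():
    bad = pd.DataFrame(
        [dict(selector="s", classifier="c", feature_set_size=1, fold=0,
              metric_name="accuracy", value=1.5)]
    )
    with pytest.raises(ValueError):
        MetricsTable(bad)
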