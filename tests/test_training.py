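"""Balanced datasets, label shuffling, bagged trees and cross-validation."""

import numpy as np
import pandas as pd
import pytest

import oncopath as op
from oncopath.training import FoldCounts, rank_auc

from conftest import random_typed_network


@pytest.fixture
def toy_setup():
    net = random_typed_network(12, 0.25, seed=1)
    cent = op.centrality_table(net)
    edges = sorted(net.simple_edges())
    positives = edges[:3]
    return net, cent, positives


class TestEdgeFeatures:
    def test_concatenation_order(self):
        cent = pd.DataFrame(
            {
                "degree": [1.0, 2.0],
                "clustering": [0.0, 1.0],
                "betweenness": [0.0, 0.0],
                "closeness": [0.5, 0.25],
            },
            index=pd.Index([7, 8], name="gene"),
        )
        x = op.build_edge_features(cent, [(7, 8)])
        assert x.tolist() == [[1, 0, 0, 0.5, 2, 1, 0, 0.25]]
        x_rev = op.build_edge_features(cent, [(8, 7)])
        assert x_rev.tolist() == [[2, 1, 0, 0.25, 1, 0, 0, 0.5]]

    def test_missing_gene_named(self, toy_setup):
        _, cent, _ = toy_setup
        with pytest.raises(KeyError, match="99999"):
            op.build_edge_features(cent, [(99999, cent.index[0])])

    def test_rows_match_lookup_oracle(self, toy_setup):
        net, cent, _ = toy_setup
        edges = sorted(net.simple_edges())[:50]
        x = op.build_edge_features(cent, edges)
        cols = ["degree", "clustering", "betweenness", "closeness"]
        for i, (s, t) in enumerate(edges):
            expected = list(cent.loc[s, cols]) + list(cent.loc[t, cols])
            assert x[i].tolist() == expected


class TestNormalDatasets:
    def test_balanced_and_sized(self, toy_setup):
        net, cent, positives = toy_setup
        for ds in op.sample_normal_datasets(net, cent, positives, 5, seed=3):
            assert len(ds) == 2 * len(positives)
            assert ds.y.sum() == len(positives)
            assert ds.kind == "normal"

    def test_contains_all_positives_and_no_overlap(self, toy_setup):
        net, cent, positives = toy_setup
        for ds in op.sample_normal_datasets(net, cent, positives, 5, seed=3):
            assert ds.edges[: len(positives)] == list(positives)
            negs = set(ds.edges[len(positives):])
            assert not negs & set(positives)
            assert len(negs) == len(positives)  # without replacement

    def test_negative_samples_match_seeded_oracle(self, toy_setup):
        net, cent, positives = toy_setup
        datasets = op.sample_normal_datasets(net, cent, positives, 4, seed=11)
        pool = sorted(net.simple_edges() - set(positives))
        rng = np.random.default_rng(11)
        for ds in datasets:
            idx = rng.choice(len(pool), size=len(positives), replace=False)
            assert ds.edges[len(positives):] == [pool[j] for j in idx]

    def test_insufficient_negatives_error(self):
        net = op.InteractionNetwork(
            [op.Interaction(1, 2, "physical"), op.Interaction(2, 3, "physical")]
        )
        cent = op.centrality_table(net)
        with pytest.raises(ValueError, match="non-positive edges"):
            op.sample_normal_datasets(net, cent, [(1, 2), (2, 3)], 1, seed=0)


class TestShuffleLabels:
    def test_label_multiset_and_features_preserved(self, toy_setup):
        net, cent, positives = toy_setup
        ds = op.sample_normal_datasets(net, cent, positives, 1, seed=5)[0]
        for sh in op.shuffle_labels(ds, 3, seed=6):
            assert sh.kind == "shuffled"
            assert sh.y.sum() == ds.y.sum()
            assert sh.X is ds.X or (sh.X == ds.X).all()

    def test_fraction_kept_near_half(self, toy_setup):
        net, cent, positives = toy_setup
        ds = op.sample_normal_datasets(net, cent, positives, 1, seed=5)[0]
        n = len(ds)
        kept = [
            (sh.y == ds.y).mean() for sh in op.shuffle_labels(ds, 400, seed=7)
        ]
        # E[kept] for a balanced dataset under uniform permutation is 1/2
        assert np.mean(kept) == pytest.approx(0.5, abs=3 / np.sqrt(400 * n))


class TestBaggedTrees:
    def separable(self, n=120, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.uniform(0, 10, size=(n, 8))
        y = (X[:, 0] > 5).astype(int)
        return X, y

    def test_contains_n_bags_trees(self, toy_setup):
        net, cent, positives = toy_setup
        ds = op.sample_normal_datasets(net, cent, positives, 1, seed=1)[0]
        model = op.train_bagged_trees(ds, n_bags=20, seed=2)
        assert len(model._trees) == 20

    def test_deterministic_given_seed(self):
        X, y = self.separable()
        grid = np.random.default_rng(9).uniform(0, 10, size=(40, 8))
        p1 = op.BaggedTreeModel(10, seed=4).fit(X, y).predict_proba_pos(grid)
        p2 = op.BaggedTreeModel(10, seed=4).fit(X, y).predict_proba_pos(grid)
        assert (p1 == p2).all()

    def test_single_class_errors(self):
        X = np.zeros((10, 8))
        with pytest.raises(ValueError, match="single class"):
            op.BaggedTreeModel(5, seed=0).fit(X, np.zeros(10, int))

    def test_learns_separable_rule(self):
        X, y = self.separable(seed=1)
        model = op.BaggedTreeModel(20, seed=3).fit(X, y)
        train_pred = model.predict_proba_pos(X) >= 0.5
        assert (train_pred == y.astype(bool)).mean() == 1.0
        Xh, yh = self.separable(n=300, seed=2)
        auc = rank_auc(
            model.predict_proba_pos(Xh[yh == 1]),
            model.predict_proba_pos(Xh[yh == 0]),
        )
        assert auc >= 0.99

    def test_laplace_bounds_probabilities_away_from_extremes(self):
        X, y = self.separable()
        model = op.BaggedTreeModel(5, seed=0).fit(X, y)
        p = model.predict_proba_pos(X)
        assert (p > 0).all() and (p < 1).all()


def all_pairs_auc(pos, neg):
    wins = sum((p > n) + 0.5 * (p == n) for p in pos for n in neg)
    return wins / (len(pos) * len(neg))


class TestCrossValidate:
    def test_recall_precision_formulas(self):
        fc = FoldCounts(tp=8, fp=0, fn=2, tn=0)
        assert fc.recall == pytest.approx(0.8)
        fc = FoldCounts(tp=6, fp=2, fn=0, tn=0)
        assert fc.precision == pytest.approx(0.75)
        assert FoldCounts(0, 0, 0, 5).precision == 0.0

    def test_auc_extremes_and_oracle(self):
        assert rank_auc(np.array([0.9, 0.8]), np.array([0.1, 0.2])) == 1.0
        rng = np.random.default_rng(0)
        for _ in range(20):
            pos = rng.uniform(size=7).round(1)  # rounding forces ties
            neg = rng.uniform(size=9).round(1)
            assert rank_auc(pos, neg) == pytest.approx(all_pairs_auc(pos, neg))

    def test_stratified_cv_report(self, toy_setup):
        net, cent, _ = toy_setup
        edges = sorted(net.simple_edges())
        positives = edges[:8]
        ds = op.sample_normal_datasets(net, cent, positives, 1, seed=1)[0]
        rep = op.cross_validate(ds, k_folds=4, n_bags=5, seed=2)
        assert len(rep.folds) == 4
        assert 0 <= rep.recall <= 1 and 0 <= rep.precision <= 1 and 0 <= rep.auc <= 1
        # fold-averaged metrics recompute from the recorded counts
        assert rep.recall == pytest.approx(np.mean([f.recall for f in rep.folds]))


def brute_force_u(a, b):
    return sum((x > y) + 0.5 * (x == y) for x in a for y in b)


class TestCompare:
    def mk_report(self, v):
        return op.PerformanceReport(recall=v, precision=v, auc=v)

    def test_identical_groups_nonsignificant(self):
        grp = [self.mk_report(v) for v in (0.5, 0.52, 0.48, 0.51)]
        cmp_rep = op.compare_normal_vs_shuffled(grp, list(grp), alpha=0.005)
        assert all(p > 0.5 for p in cmp_rep.p_values.values())
        assert not any(cmp_rep.significant.values())

    def test_u_statistic_matches_brute_force(self):
        from scipy import stats

        a = [0.9, 0.9, 0.88]
        b = [0.5, 0.49, 0.51]
        u = stats.mannwhitneyu(a, b, alternative="two-sided").statistic
        assert u == brute_force_u(a, b)

    def test_medians_reported(self):
        g1 = [self.mk_report(v) for v in (0.9, 0.88, 0.92)]
        g2 = [self.mk_report(v) for v in (0.5, 0.49, 0.51)]
        rep = op.compare_normal_vs_shuffled(g1, g2)
        assert rep.medians_normal["auc"] == pytest.approx(np.median([0.9, 0.88, 0.92]))
        assert rep.medians_shuffled["recall"] == pytest.approx(0.5)

    def test_empty_group_errors(self):
        with pytest.raises(ValueError):
            op.compare_normal_vs_shuffled([], [self.mk_report(0.5)])
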