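import json

import numpy as np
import pytest

from genegraph.balancing import (balance_and_split, save_split_manifest,
                                 split_nodes, upsample)

from conftest import graph_from_edges, random_graph


def two_class_graph():
    # classes {0: 4 nodes, 1: 2 nodes}
    return graph_from_edges(6, [(0, 1), (1, 2), (2, 3), (3, 4), (4, 5)],
                            [0, 0, 0, 0, 1, 1])


def four_class_graph():
    # class sizes {8, 4, 2, 1}
    labels = [0] * 8 + [1] * 4 + [2] * 2 + [3]
    rng = np.random.default_rng(3)
    edges = {tuple(sorted(e)) for e in rng.integers(0, 15, size=(40, 2))
             if e[0] != e[1]}
    return graph_from_edges(15, sorted(edges), labels, task="multiclass")


class TestUpsample:
    def test_minority_duplicated_to_majority(self):
        bal = upsample(two_class_graph(), seed=0)
        assert bal.graph.n_nodes == 8
        assert bal.counts_after == {"No Risk": 4, "Risk": 4}
        assert all(bal.graph.labels[k] == bal.graph.labels[s]
                   for k, s in bal.origin.items())

    def test_already_balanced_graph_unchanged(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)], [0, 0, 1, 1])
        bal = upsample(g, seed=0)
        assert bal.origin == {}
        assert (bal.graph.adjacency != g.adjacency).nnz == 0

    def test_four_class_fixture_counts(self):
        # balancing {8,4,2,1} to the majority adds 0+4+6+7 = 17 nodes
        bal = upsample(four_class_graph(), seed=1)
        assert len(bal.origin) == 17
        assert bal.graph.n_nodes == 32
        assert set(bal.counts_after.values()) == {8}
        assert (bal.graph.adjacency != bal.graph.adjacency.T).nnz == 0

    def test_duplicate_degree_equals_source_degree(self):
        bal = upsample(four_class_graph(), seed=2)
        deg = np.asarray(bal.graph.adjacency.sum(axis=1)).ravel()
        for new, src in bal.origin.items():
            assert deg[new] == deg[src]

    def test_duplicates_inherit_features_and_never_link_to_source(self):
        bal = upsample(four_class_graph(), seed=2)
        a = bal.graph.adjacency
        for new, src in bal.origin.items():
            assert (bal.graph.features[[new]] !=
                    bal.graph.features[[src]]).nnz == 0
            assert a[new, src] == 0

    def test_original_edges_untouched(self):
        g = four_class_graph()
        n = g.n_nodes
        bal = upsample(g, seed=5)
        sub = bal.graph.adjacency[:n][:, :n]
        assert (sub != g.adjacency).nnz == 0

    def test_empty_class_rejected(self):
        g = graph_from_edges(4, [(0, 1), (2, 3)], [0, 0, 1, 1],
                             task="multiclass")   # classes 2,3 empty
        with pytest.raises(ValueError, match="empty class"):
            upsample(g)

    def test_deterministic_per_seed(self):
        g = four_class_graph()
        b1, b2 = upsample(g, seed=9), upsample(g, seed=9)
        assert b1.origin == b2.origin

    def test_interpolate_mode_keeps_class_and_convexity(self):
        g = random_graph(30, 0.3, seed=4)
        bal = upsample(g, mode="interpolate", seed=1)
        sums = np.asarray(bal.graph.features.sum(axis=1)).ravel()
        n = g.n_nodes
        base = np.asarray(g.features.sum(axis=1)).ravel()
        for new, src in bal.origin.items():
            row = bal.graph.features[[new]].todense()
            assert row.min() >= 0
            assert bal.graph.labels[new] == g.labels[src]
        assert sums[:n] == pytest.approx(base)


class TestSplit:
    def test_stratified_quarter_split(self):
        labels = np.array([0] * 16 + [1] * 12)
        train, test = split_nodes(labels, 0.25, seed=0)
        assert test.size == 7 and train.size == 21
        assert (labels[test] == 1).sum() == 3    # 12 * 0.25

    def test_same_seed_identical(self):
        labels = np.array([0, 1] * 20)
        assert np.array_equal(split_nodes(labels, 0.25, seed=3)[1],
                              split_nodes(labels, 0.25, seed=3)[1])

    def test_disjoint_and_exhaustive(self):
        labels = np.array([0, 1, 2, 3] * 10)
        train, test = split_nodes(labels, 0.25, seed=1)
        assert np.array_equal(np.sort(np.r_[train, test]),
                              np.arange(labels.size))

    def test_tiny_class_rejected(self):
        with pytest.raises(ValueError):
            split_nodes(np.array([0] * 20 + [1]), 0.25, seed=0)

    def test_leakage_safe_protocol_excludes_test_sources(self):
        g = random_graph(40, 0.2, seed=8)
        bal, train, test = balance_and_split(g, protocol="before_upsample",
                                             seed=2)
        sources = set(bal.origin.values())
        assert sources.isdisjoint(set(test.tolist()))
        assert np.array_equal(np.sort(np.r_[
            train[train < g.n_nodes], test]), np.arange(g.n_nodes))

    def test_after_upsample_protocol_balances_then_splits(self):
        g = two_class_graph()
        bal, train, test = balance_and_split(g, protocol="after_upsample",
                                             seed=0)
        assert train.size + test.size == bal.graph.n_nodes
        assert set(train.tolist()).isdisjoint(test.tolist())

    def test_manifest_roundtrip(self, tmp_path):
        path = tmp_path / "split.json"
        save_split_manifest(path, "after_upsample", 5, [0, 1], [2])
        m = json.loads(path.read_text())
        assert m == {"protocol": "after_upsample", "seed": 5,
                     "train_indices": [0, 1], "test_indices": [2]}
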