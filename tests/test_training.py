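import numpy as np
import pytest
import scipy.sparse as sp

from genegraph.io import GeneGraph
from genegraph.model import GeneNodeClassifier, TrainConfig

from conftest import graph_from_edges, random_graph


def separable_graph(n=20):
    """Two feature-separated classes, linearly separable by construction."""
    rng = np.random.default_rng(0)
    labels = np.r_[np.zeros(n // 2, int), np.ones(n // 2, int)]
    feats = rng.normal(size=(n, 3)) * 0.1
    feats[labels == 1, 0] += 5.0
    edges = [(i, i + 1) for i in range(n - 1)]
    return graph_from_edges(n, edges, labels, features=feats)


@pytest.mark.parametrize("family", ["mlp", "sage"])
def test_separable_fixture_reaches_perfect_train_accuracy(family):
    g = separable_graph()
    clf = GeneNodeClassifier(g, family=family, hidden_dim=8)
    res = clf.fit(config=TrainConfig(epochs=200, learning_rate=0.01, seed=0))
    train_rep = res.evaluate(np.arange(g.n_nodes))
    assert train_rep.accuracy == 100.0


@pytest.mark.parametrize("family", ["gcn", "transformer", "mlp"])
def test_same_seed_gives_identical_loss_traces(family):
    g = random_graph(15, 0.3, seed=2)
    cfg = TrainConfig(epochs=15, learning_rate=0.01, seed=4)
    t1 = GeneNodeClassifier(g, family=family, hidden_dim=8).fit(config=cfg)
    t2 = GeneNodeClassifier(g, family=family, hidden_dim=8).fit(config=cfg)
    assert np.array_equal(t1.loss_trace, t2.loss_trace)


def test_zero_learning_rate_freezes_loss():
    g = random_graph(12, 0.3, seed=1)
    res = GeneNodeClassifier(g, family="gcn", hidden_dim=4).fit(
        config=TrainConfig(epochs=10, learning_rate=0.0, weight_decay=0.0))
    assert np.allclose(res.loss_trace, res.loss_trace[0])


def test_empty_training_set_rejected():
    g = random_graph(10, 0.3, seed=1)
    with pytest.raises(ValueError):
        GeneNodeClassifier(g, family="mlp").fit(
            np.array([], dtype=int), TrainConfig(epochs=1))


def test_patience_stops_early_when_loss_plateaus():
    g = separable_graph(12)
    res = GeneNodeClassifier(g, family="gcn", hidden_dim=4).fit(
        config=TrainConfig(epochs=500, learning_rate=0.0, weight_decay=0.0,
                           patience=3))
    assert res.loss_trace.size == 5   # first epoch + 3 stalls + stop epoch


def test_loss_trace_recorded_every_epoch():
    g = random_graph(10, 0.3, seed=3)
    res = GeneNodeClassifier(g, family="sage", hidden_dim=4).fit(
        config=TrainConfig(epochs=7, learning_rate=0.01))
    assert res.loss_trace.shape == (7,) and np.isfinite(res.loss_trace).all()


@pytest.fixture(scope="module")
def fitted():
    g = separable_graph(24)
    clf = GeneNodeClassifier(g, family="sage", hidden_dim=8)
    res = clf.fit(np.arange(18),
                  TrainConfig(epochs=150, learning_rate=0.01, seed=0))
    return g, res


class TestResultsSurface:

    def test_predict_proba_rows_normalise(self, fitted):
        _, res = fitted
        proba = res.predict_proba()
        assert np.allclose(proba.sum(axis=1), 1.0, atol=1e-6)

    def test_top_genes_k1_is_argmax(self, fitted):
        g, res = fitted
        proba = res.predict_proba()
        [(gene, conf)] = res.top_genes("Risk", k=1)
        ci = g.classes.index("Risk")
        pool = np.flatnonzero(proba.argmax(axis=1) == ci)
        assert conf == pytest.approx(proba[pool, ci].max())
        assert gene == g.nodes[pool[np.argmax(proba[pool, ci])]]

    def test_top_genes_truncates_with_warning(self, fitted):
        _, res = fitted
        with pytest.warns(UserWarning, match="shorter"):
            lst = res.top_genes("Risk", k=500)
        assert 0 < len(lst) < 500
        confs = [c for _, c in lst]
        assert confs == sorted(confs, reverse=True)

    def test_unknown_class_rejected(self, fitted):
        _, res = fitted
        with pytest.raises(ValueError):
            res.top_genes("Mystery", k=3)

    def test_projection_shape_and_determinism(self, fitted):
        _, res = fitted
        p1 = res.project_embeddings(seed=3, perplexity=5)
        p2 = res.project_embeddings(seed=3, perplexity=5)
        assert p1.shape == (24, 2)
        assert np.array_equal(p1, p2)

    def test_projection_perplexity_guard(self, fitted):
        _, res = fitted
        with pytest.raises(ValueError, match="perplexity"):
            res.project_embeddings(perplexity=30)

    def test_summary_mentions_key_fields(self, fitted):
        _, res = fitted
        text = res.summary(test_idx=np.arange(18, 24))
        for token in ("sage", "binary", "Accuracy", "train nodes"):
            assert token in text

    def test_evaluate_original_only_filters_duplicates(self):
        from genegraph.balancing import balance_and_split
        g = random_graph(40, 0.2, seed=6)
        bal, train, test = balance_and_split(g, seed=1)
        res = GeneNodeClassifier(bal, family="mlp", hidden_dim=4).fit(
            train, TrainConfig(epochs=5, learning_rate=0.01))
        full = res.evaluate(test)
        orig = res.evaluate(test, original_only=True)
        assert orig.confusion.sum() <= full.confusion.sum()
        assert orig.confusion.sum() == (test < g.n_nodes).sum()


def test_featureless_modes():
    g = random_graph(10, 0.3, seed=5)
    ones = GeneNodeClassifier(g, family="gcn", featureless=True)
    assert ones.X.shape == (10, 1)
    ident = GeneNodeClassifier(g, family="gcn", featureless=True,
                               featureless_mode="identity")
    assert ident.X.shape == (10, 10)
    with pytest.raises(ValueError):
        GeneNodeClassifier(g, featureless=True, featureless_mode="random")
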