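import numpy as np
import pytest
import scipy.sparse as sp

from genegraph.io import GeneGraph, GeneRecord, GeneTable
from genegraph.synthetic import SyntheticCohortConfig, generate_cohort


def make_table(rows):
    """GeneTable from (symbol, band, score, syndromic) tuples."""
    return GeneTable(GeneRecord(*r) for r in rows)


def graph_from_edges(n, edges, labels, task="binary", features=None):
    """Small GeneGraph with given undirected edges and integer labels."""
    rows = [e[0] for e in edges] + [e[1] for e in edges]
    cols = [e[1] for e in edges] + [e[0] for e in edges]
    adj = sp.coo_array((np.ones(len(rows)), (rows, cols)), shape=(n, n)).tocsr()
    adj.data[:] = 1.0
    if features is None:
        features = sp.eye_array(n, format="csr")
    return GeneGraph([f"g{i}" for i in range(n)], adj, sp.csr_array(features),
                     np.asarray(labels), task, [f"band{j}" for j in
                                                range(features.shape[1])])


def random_graph(n, p, seed, n_feats=5, n_classes=2, task="binary"):
    rng = np.random.default_rng(seed)
    upper = np.triu(rng.random((n, n)) < p, k=1)
    dense = (upper | upper.T).astype(float)
    feats = rng.random((n, n_feats))
    labels = rng.integers(0, n_classes, size=n)
    task = {2: "binary", 4: "multiclass"}[n_classes]
    return GeneGraph([f"g{i}" for i in range(n)], sp.csr_array(dense),
                     sp.csr_array(feats), labels, task,
                     [f"b{j}" for j in range(n_feats)])


@pytest.fixture(scope="session")
def small_cohort(tmp_path_factory):
    """A ~300-gene planted cohort shared across read-only tests."""
    cfg = SyntheticCohortConfig.scaled(40, seed=11)
    return generate_cohort(cfg, tmp_path_factory.mktemp("cohort"))


@pytest.fixture(scope="session")
def medium_cohort(tmp_path_factory):
    """The ~1,222-gene default study cohort (one seed)."""
    cfg = SyntheticCohortConfig.scaled(10, seed=5)
    return generate_cohort(cfg, tmp_path_factory.mktemp("cohort_med"))
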