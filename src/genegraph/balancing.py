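"""Class balancing by graph-aware node duplication, and train/test splitting.

Minority classes are upsampled to the majority count by sampling source nodes
with replacement.  Each duplicate takes a copy of its source's feature row and
of its adjacency row/column, so the balanced adjacency is the submatrix
``A[ix][:, ix]`` with ``ix = originals + sampled sources`` — duplicates inherit
every connection of their source (including connections to other duplicates of
the source's neighbours) but are not linked to the source itself, and edges
among original nodes are untouched.

Two split protocols are provided: splitting the balanced node set (the
protocol the analysis this package reproduces used) and a leakage-safe
alternative that splits original nodes first and upsamples only the training
side, so no test gene has a duplicate in training.  The leakage-safe protocol
is the one we recommend for real use; see docs/methods.md.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np
import scipy.sparse as sp
from sklearn.model_selection import train_test_split

from .io import GeneGraph

PROTOCOLS = ("after_upsample", "before_upsample")
MODES = ("duplicate", "interpolate")


@dataclass
class BalancedGraph:
    graph: GeneGraph
    origin: dict                      # new node index -> source node index
    counts_before: dict
    counts_after: dict

    @property
    def n_original(self) -> int:
        return self.graph.n_nodes - len(self.origin)

    def original_indices(self) -> np.ndarray:
        return np.arange(self.n_original)


def _interpolated_features(feats: sp.csr_array, labels: np.ndarray,
                           adj: sp.csr_array, sources: np.ndarray,
                           rng: np.random.Generator) -> sp.csr_array:
    """Convex mix of each source's features with a same-class neighbour's."""
    rows = []
    indptr, indices = adj.indptr, adj.indices
    for s in sources:
        nbrs = indices[indptr[s]:indptr[s + 1]]
        nbrs = nbrs[labels[nbrs] == labels[s]]
        lam = rng.random()
        if nbrs.size:
            partner = rng.choice(nbrs)
            rows.append(lam * feats[[s]] + (1 - lam) * feats[[partner]])
        else:
            rows.append(feats[[s]])
    return sp.vstack(rows).tocsr() if rows else feats[[]]


def upsample(graph: GeneGraph, mode: str = "duplicate",
             seed: int = 0) -> BalancedGraph:
    """Upsample every minority class to the majority count."""
    return _upsample(graph, mode=mode, seed=seed, source_pool=None, target=None)


def _upsample(graph: GeneGraph, mode: str, seed: int,
              source_pool: Optional[np.ndarray],
              target: Optional[int]) -> BalancedGraph:
    if mode not in MODES:
        raise ValueError(f"mode must be one of {MODES}")
    labels = graph.labels
    classes = np.arange(len(graph.classes))
    present = [c for c in classes if (labels == c).sum() > 0]
    if len(present) < 2:
        raise ValueError("need at least 2 classes present to balance")

    pool_mask = np.zeros(graph.n_nodes, dtype=bool)
    pool_mask[source_pool if source_pool is not None
              else np.arange(graph.n_nodes)] = True
    pool_counts = {c: int((labels[pool_mask] == c).sum()) for c in classes}
    if target is None:
        target = max(pool_counts.values())
    counts_before = {graph.classes[c]: int((labels == c).sum()) for c in classes}

    rng = np.random.default_rng(seed)
    new_sources = []
    for c in classes:
        need = target - pool_counts[c]
        if need <= 0:
            continue
        members = np.flatnonzero(pool_mask & (labels == c))
        if members.size == 0:
            raise ValueError(
                f"cannot upsample empty class {graph.classes[c]!r}")
        new_sources.append(rng.choice(members, size=need, replace=True))
    new_sources = (np.concatenate(new_sources) if new_sources
                   else np.array([], dtype=int))

    n = graph.n_nodes
    ix = np.r_[np.arange(n), new_sources]
    adj = graph.adjacency[ix][:, ix].tocsr()
    if mode == "duplicate" or new_sources.size == 0:
        feats = graph.features[ix].tocsr()
    else:
        feats = sp.vstack([
            graph.features,
            _interpolated_features(graph.features, labels, graph.adjacency,
                                   new_sources, rng),
        ]).tocsr()
    new_labels = np.r_[labels, labels[new_sources]]
    nodes = list(graph.nodes) + [f"{graph.nodes[s]}#dup{k}"
                                 for k, s in enumerate(new_sources)]
    bal = GeneGraph(nodes, adj, feats, new_labels, graph.task,
                    list(graph.band_vocab))
    origin = {n + k: int(s) for k, s in enumerate(new_sources)}
    counts_after = {graph.classes[c]: int((new_labels == c).sum())
                    for c in classes}
    return BalancedGraph(bal, origin, counts_before, counts_after)


def split_nodes(labels: np.ndarray, test_fraction: float = 0.25,
                seed: int = 0):
    """Stratified-by-class random split of node indices."""
    if not 0.0 < test_fraction < 1.0:
        raise ValueError("test_fraction must be in (0, 1)")
    idx = np.arange(labels.shape[0])
    present, counts = np.unique(labels, return_counts=True)
    if (counts < 2).any():
        raise ValueError("every class needs >= 2 members to stratify")
    n_test = int(round(test_fraction * idx.size))
    if n_test < present.size or idx.size - n_test < present.size:
        raise ValueError("split would leave an empty class on one side")
    train, test = train_test_split(idx, test_size=test_fraction,
                                   stratify=labels, random_state=seed)
    return np.sort(train), np.sort(test)


def balance_and_split(graph: GeneGraph, protocol: str = "after_upsample",
                      test_fraction: float = 0.25, mode: str = "duplicate",
                      seed: int = 0):
    """Balance the graph and split into train/test under the chosen protocol.

    Returns ``(balanced, train_idx, test_idx)``.  With ``after_upsample`` the
    balanced node set is split; with ``before_upsample`` the original nodes
    are split first and only training-side nodes are eligible duplication
    sources, so train and test never share a gene.
    """
    if protocol not in PROTOCOLS:
        raise ValueError(f"protocol must be one of {PROTOCOLS}")
    if protocol == "after_upsample":
        bal = upsample(graph, mode=mode, seed=seed)
        train, test = split_nodes(bal.graph.labels, test_fraction, seed=seed)
        return bal, train, test
    train0, test0 = split_nodes(graph.labels, test_fraction, seed=seed)
    bal = _upsample(graph, mode=mode, seed=seed, source_pool=train0,
                    target=None)
    added = np.arange(graph.n_nodes, bal.graph.n_nodes)
    return bal, np.sort(np.r_[train0, added]), test0


def save_split_manifest(path, protocol: str, seed: int,
                        train_idx, test_idx) -> None:
    Path(path).write_text(json.dumps({
        "protocol": protocol,
        "seed": int(seed),
        "train_indices": np.asarray(train_idx).tolist(),
        "test_indices": np.asarray(test_idx).tolist(),
    }, indent=2) + "\n")
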