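"""Model / Results interface for gene-graph node classification.

``GeneNodeClassifier`` is built from a (possibly balanced) gene graph and a
model family; ``fit()`` trains it and returns a ``NodeClassifierResults``
carrying the learned weights, the loss trace, prediction and evaluation
methods, ranked confidence gene lists, 2-D embedding projections and a
``summary()`` table::

    model = GeneNodeClassifier(balanced, family="sage")
    res = model.fit(train_idx, TrainConfig(epochs=200), seed=0)
    report = res.evaluate(test_idx)
    print(res.summary())

Training follows a fixed regimen: AdamW (decoupled weight decay) minimising
the negative log-likelihood of the log-softmax outputs on the training nodes.
Graph families do full-graph message passing, so they train full-batch and
the batch size is only honoured for the MLP baseline, which is trained on
true mini-batches.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, replace
from typing import Optional, Sequence, Union

import numpy as np

from .autodiff import AdamW, Tensor, nll_loss
from .balancing import BalancedGraph
from .io import GeneGraph
from .metrics import MetricsReport, compute_report
from .models import ModelSpec, forward, init_params

logger = logging.getLogger(__name__)

FEATURELESS_MODES = ("ones", "identity")


@dataclass(frozen=True)
class TrainConfig:
    """Training regimen (defaults follow the reproduced experiment)."""

    learning_rate: float = 0.001
    weight_decay: float = 5e-4
    epsilon: float = 1e-4          # AdamW numerical-stability epsilon
    batch_size: int = 64           # honoured by the MLP family only
    epochs: int = 5000
    seed: int = 0
    patience: Optional[int] = None  # early stopping; off by default

    def __post_init__(self):
        if self.epochs < 1 or self.batch_size < 1:
            raise ValueError("epochs and batch_size must be positive")
        if self.learning_rate < 0:
            raise ValueError("learning_rate must be nonnegative")


class GeneNodeClassifier:
    """A node classifier over a gene-interaction graph.

    Parameters
    ----------
    graph : GeneGraph or BalancedGraph
        The (optionally class-balanced) graph to classify nodes of.
    family : {"gcn", "sage", "transformer", "mlp"}
    featureless : bool
        Replace node features by an uninformative surrogate (ablation mode).
    featureless_mode : {"ones", "identity"}
        Constant-column or node-indicator surrogate.
    Remaining keyword arguments override :class:`~genegraph.models.ModelSpec`
    fields (hidden_dim, attention, gcn_normalization, ...).
    """

    def __init__(self, graph: Union[GeneGraph, BalancedGraph],
                 family: str = "sage", featureless: bool = False,
                 featureless_mode: str = "ones", **spec_overrides):
        if isinstance(graph, BalancedGraph):
            self.balanced: Optional[BalancedGraph] = graph
            self.graph = graph.graph
        else:
            self.balanced = None
            self.graph = graph
        self.spec = ModelSpec(family=family, **spec_overrides)
        self.featureless = featureless
        if featureless_mode not in FEATURELESS_MODES:
            raise ValueError(f"featureless_mode must be in {FEATURELESS_MODES}")
        self.featureless_mode = featureless_mode
        n = self.graph.n_nodes
        if featureless:
            self.X = (np.ones((n, 1)) if featureless_mode == "ones"
                      else np.eye(n))
        else:
            self.X = np.asarray(self.graph.features.todense(), dtype=np.float64)

    @classmethod
    def from_tables(cls, genes, interactions, task: str, family: str = "sage",
                    **kw) -> "GeneNodeClassifier":
        """Build directly from a parsed gene table and human-filtered
        interaction records."""
        from .io import build_graph
        return cls(build_graph(genes, interactions, task), family=family, **kw)

    @property
    def n_original(self) -> int:
        return (self.balanced.n_original if self.balanced is not None
                else self.graph.n_nodes)

    # -- fitting --------------------------------------------------------
    def fit(self, train_idx: Optional[Sequence[int]] = None,
            config: Optional[TrainConfig] = None,
            seed: Optional[int] = None) -> "NodeClassifierResults":
        config = config or TrainConfig()
        if seed is not None:
            config = replace(config, seed=seed)
        train_idx = (np.arange(self.graph.n_nodes) if train_idx is None
                     else np.asarray(train_idx, dtype=int))
        if train_idx.size == 0:
            raise ValueError("training index set is empty")
        y = self.graph.labels
        n_classes = len(self.graph.classes)
        params = init_params(self.spec, self.X.shape[1], n_classes,
                             seed=config.seed)
        opt = AdamW(params.values(), lr=config.learning_rate,
                    eps=config.epsilon, weight_decay=config.weight_decay)
        rng = np.random.default_rng(config.seed + 1)
        adj = self.graph.adjacency
        trace = np.empty(config.epochs)
        best = np.inf
        stall = 0
        mlp_batches = self.spec.family == "mlp"
        if not mlp_batches and config.batch_size != 64:
            logger.info("batch_size ignored for full-graph family %r",
                        self.spec.family)
        epochs_run = config.epochs
        for epoch in range(config.epochs):
            if mlp_batches:
                order = rng.permutation(train_idx)
                losses = []
                for lo in range(0, order.size, config.batch_size):
                    batch = order[lo:lo + config.batch_size]
                    logp = forward(self.spec, params, adj, self.X[batch])
                    loss = nll_loss(logp, y[batch])
                    opt.zero_grad()
                    loss.backward()
                    opt.step()
                    losses.append(float(loss.data))
                trace[epoch] = float(np.mean(losses))
            else:
                logp = forward(self.spec, params, adj, self.X)
                loss = nll_loss(logp.rows(train_idx), y[train_idx])
                opt.zero_grad()
                loss.backward()
                opt.step()
                trace[epoch] = float(loss.data)
            if not np.isfinite(trace[epoch]):
                raise RuntimeError(
                    f"non-finite training loss at epoch {epoch}: "
                    f"{trace[epoch]} (family={self.spec.family})")
            if config.patience is not None:
                if trace[epoch] < best - 1e-9:
                    best, stall = trace[epoch], 0
                else:
                    stall += 1
                    if stall > config.patience:
                        epochs_run = epoch + 1
                        break
        return NodeClassifierResults(self, params, trace[:epochs_run],
                                     train_idx, config)


class NodeClassifierResults:
    """Fitted-state container returned by :meth:`GeneNodeClassifier.fit`."""

    def __init__(self, model: GeneNodeClassifier, params, loss_trace,
                 train_idx, config: TrainConfig):
        self.model = model
        self.params = params
        self.loss_trace = np.asarray(loss_trace)
        self.train_idx = np.asarray(train_idx)
        self.config = config
        self._logp_cache: Optional[np.ndarray] = None
        self._hidden_cache: Optional[np.ndarray] = None

    # -- prediction -----------------------------------------------------
    def _full_forward(self):
        if self._logp_cache is None:
            logp, hidden = forward(self.model.spec, self.params,
                                   self.model.graph.adjacency, self.model.X,
                                   return_hidden=True)
            self._logp_cache = logp.data
            self._hidden_cache = hidden.data
        return self._logp_cache

    def predict_log_proba(self, idx=None) -> np.ndarray:
        logp = self._full_forward()
        return logp if idx is None else logp[np.asarray(idx, dtype=int)]

    def predict_proba(self, idx=None) -> np.ndarray:
        return np.exp(self.predict_log_proba(idx))

    def predict(self, idx=None) -> np.ndarray:
        return self.predict_log_proba(idx).argmax(axis=1)

    def embeddings(self) -> np.ndarray:
        """Penultimate-layer node embeddings."""
        self._full_forward()
        return self._hidden_cache

    # -- evaluation -----------------------------------------------------
    def evaluate(self, test_idx, original_only: bool = False) -> MetricsReport:
        """Metrics report on the given test nodes.

        ``original_only`` restricts evaluation to non-duplicate nodes, for
        the leakage-aware reading of the balanced-split protocol.
        """
        test_idx = np.asarray(test_idx, dtype=int)
        if original_only:
            test_idx = test_idx[test_idx < self.model.n_original]
        y = self.model.graph.labels[test_idx]
        proba = self.predict_proba(test_idx)
        return compute_report(y, proba.argmax(axis=1), proba,
                              self.model.graph.classes)

    def top_genes(self, class_name: str, k: int = 10,
                  original_only: bool = True) -> list:
        """The k highest-confidence genes among nodes *predicted* as the class.

        Returns ``(gene, confidence)`` pairs, confidence descending.
        """
        classes = self.model.graph.classes
        if class_name not in classes:
            raise ValueError(f"unknown class {class_name!r}; have {classes}")
        ci = classes.index(class_name)
        proba = self.predict_proba()
        pool = np.arange(self.model.n_original if original_only
                         else self.model.graph.n_nodes)
        pool = pool[proba[pool].argmax(axis=1) == ci]
        if pool.size < k:
            warnings.warn(
                f"only {pool.size} nodes predicted as {class_name!r}; "
                f"returning a shorter list than k={k}")
        order = pool[np.argsort(-proba[pool, ci], kind="stable")][:k]
        return [(self.model.graph.nodes[i], float(proba[i, ci]))
                for i in order]

    def project_embeddings(self, idx=None, seed: int = 0,
                           perplexity: float = 30.0) -> np.ndarray:
        """2-D t-SNE projection of the penultimate embeddings (seeded)."""
        from sklearn.manifold import TSNE
        emb = self.embeddings()
        if idx is not None:
            emb = emb[np.asarray(idx, dtype=int)]
        if emb.shape[0] < 3 * perplexity:
            raise ValueError(
                f"n={emb.shape[0]} is too small for perplexity={perplexity}; "
                "use perplexity <= n/3")
        tsne = TSNE(n_components=2, perplexity=perplexity, random_state=seed,
                    init="pca")
        return tsne.fit_transform(emb)

    # -- reporting ------------------------------------------------------
    def summary(self, test_idx=None) -> str:
        g = self.model.graph
        train_report = self.evaluate(self.train_idx)
        lines = [
            "Gene-graph node classifier",
            "=" * 42,
            f"family:        {self.model.spec.family}"
            + (" (featureless)" if self.model.featureless else ""),
            f"task:          {g.task} ({len(g.classes)} classes)",
            f"nodes/edges:   {g.n_nodes} / {g.n_edges}",
            f"train nodes:   {self.train_idx.size}",
            f"epochs run:    {self.loss_trace.size}",
            f"final loss:    {self.loss_trace[-1]:.4f}",
            f"train accuracy: {train_report.accuracy:.2f}%",
        ]
        if test_idx is not None:
            rep = self.evaluate(test_idx)
            lines += ["", "Test metrics", "-" * 42, rep.summary()]
        return "\n".join(lines)

    def save(self, path) -> None:
        from .models import save_checkpoint
        save_checkpoint(path, self.model.spec, self.params,
                        meta={"task": self.model.graph.task,
                              "seed": self.config.seed,
                              "featureless": self.model.featureless})
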