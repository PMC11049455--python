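"""Message-passing and attention layers, written against the autodiff Tensor.

Each layer implements one aggregation rule on row-vector node embeddings h:

* ``gcn_layer`` — normalised neighbour sum, sigma( sum_{u in N(v)} (1/c_v) W h_u ),
  with optional self-loops and row (c_v = deg v) or symmetric
  (c_v = sqrt(deg v * deg u)) normalisation;
* ``sage_layer`` — neighbour aggregate (mean or sum) concatenated with the
  node's own embedding, then linearly transformed;
* ``dense_attention_layer`` — all-pair softmax attention over learned
  query/key/value projections;
* ``kernelized_attention_layer`` — the linear-time reformulation in which a
  nonnegative feature map phi replaces the softmax kernel so the two global
  sums  sum_v phi(k_v) v_v^T  and  sum_w phi(k_w)  are computed once and
  shared across all nodes.
"""

from __future__ import annotations

import logging
from typing import Callable, Optional

import numpy as np
import scipy.sparse as sp

from .autodiff import Tensor, as_tensor, concat, spmm

logger = logging.getLogger(__name__)

_relu = lambda t: t.relu()  # noqa: E731

PHI_MAPS = ("positive_rf", "exp", "elu1")


def _activation(act) -> Optional[Callable]:
    if act is None or callable(act):
        return act
    if act == "relu":
        return _relu
    if act == "identity":
        return None
    raise ValueError(f"unknown activation {act!r}")


def normalize_adjacency(adjacency, normalization: str = "row",
                        self_loops: bool = False) -> sp.csr_array:
    """Degree-normalised (optionally self-looped) adjacency operator."""
    a = sp.csr_array(adjacency, dtype=np.float64)
    if self_loops:
        a = (a + sp.eye_array(a.shape[0], format="csr")).tocsr()
    deg = np.asarray(a.sum(axis=1)).ravel()
    if (deg == 0).any() and not getattr(normalize_adjacency, "_warned", False):
        logger.warning("%d isolated node(s): zero message under normalisation "
                       "(reported once)", int((deg == 0).sum()))
        normalize_adjacency._warned = True
    with np.errstate(divide="ignore"):
        if normalization == "row":
            inv = np.where(deg > 0, 1.0 / deg, 0.0)
            return (sp.diags_array(inv) @ a).tocsr()
        if normalization == "symmetric":
            inv_sqrt = np.where(deg > 0, 1.0 / np.sqrt(deg), 0.0)
            d = sp.diags_array(inv_sqrt)
            return (d @ a @ d).tocsr()
    raise ValueError(f"unknown normalization {normalization!r}")


def gcn_layer(h, adjacency, W, normalization: str = "row",
              self_loops: bool = False, activation="relu") -> Tensor:
    """Graph-convolution propagation layer."""
    h, W = as_tensor(h), as_tensor(W)
    an = normalize_adjacency(adjacency, normalization, self_loops)
    out = spmm(an, h) @ W
    act = _activation(activation)
    return act(out) if act else out


def sage_layer(h, adjacency, W, aggregate: str = "mean",
               activation="relu") -> Tensor:
    """GraphSAGE layer: [self || neighbour-aggregate] then linear transform.

    ``W`` must have 2*d input rows.  Isolated nodes aggregate a zero vector.
    """
    h, W = as_tensor(h), as_tensor(W)
    if aggregate == "mean":
        an = normalize_adjacency(adjacency, "row", self_loops=False)
    elif aggregate == "sum":
        an = sp.csr_array(adjacency, dtype=np.float64)
    else:
        raise ValueError(f"unknown aggregate {aggregate!r}")
    agg = spmm(an, h)
    out = concat([h, agg], axis=1) @ W
    act = _activation(activation)
    return act(out) if act else out


def dense_attention_layer(z, W_Q, W_K, W_V) -> Tensor:
    """All-pair softmax attention: z_u' = sum_v softmax_v(q_u . k_v) v_v."""
    z, W_Q, W_K, W_V = map(as_tensor, (z, W_Q, W_K, W_V))
    q, k, v = z @ W_Q, z @ W_K, z @ W_V
    scores = q @ k.T
    attn = scores.log_softmax().exp()    # stabilised row softmax
    return attn @ v


def random_feature_matrix(m: int, dim: int, seed: int) -> np.ndarray:
    """Gaussian projection for the positive random-feature map."""
    return np.random.default_rng(seed).standard_normal((m, dim))


def _phi(x: Tensor, phi: str, proj: Optional[np.ndarray]) -> Tensor:
    if phi == "exp":
        # exact softmax kernel for 1-D queries/keys: exp(qk) = exp(q) exp(k)
        shift = float(x.data.max())
        return (x - shift).exp()
    if phi == "elu1":
        # elu(x) + 1 = 1 + x for x > 0, exp(x) otherwise (strictly positive)
        neg = (-((-x).relu())).exp()
        return neg + x.relu()
    if phi == "positive_rf":
        if proj is None:
            raise ValueError("positive_rf needs a projection matrix")
        m = proj.shape[0]
        sq = (x * x).sum(axis=1, keepdims=True) * 0.5
        logits = x @ Tensor(proj.T) - sq
        shift = float(logits.data.max())       # detached, cancels in the ratio
        return (logits - shift).exp() * (1.0 / np.sqrt(m))
    raise ValueError(f"unknown feature map {phi!r}, expected one of {PHI_MAPS}")


def kernelized_attention_layer(z, W_Q, W_K, W_V, phi: str = "positive_rf",
                               n_random_features: int = 64,
                               seed: int = 0) -> Tensor:
    """Linear-attention layer sharing precomputed global key/value sums.

    With phi nonnegative,  z_u' = phi(q_u)^T [sum_v phi(k_v) v_v^T] /
    phi(q_u)^T [sum_w phi(k_w)] ; both bracketed sums are independent of u and
    computed once, so the layer costs O(N) in the node count.
    """
    z, W_Q, W_K, W_V = map(as_tensor, (z, W_Q, W_K, W_V))
    q, k, v = z @ W_Q, z @ W_K, z @ W_V
    proj = (random_feature_matrix(n_random_features, k.shape[1], seed)
            if phi == "positive_rf" else None)
    pq, pk = _phi(q, phi, proj), _phi(k, phi, proj)
    kv_sum = pk.T @ v                                   # m x d, computed once
    k_sum = pk.sum(axis=0, keepdims=True)               # 1 x m, computed once
    denom = pq @ k_sum.T                                # n x 1
    if np.abs(denom.data).min() < 1e-300:
        raise FloatingPointError(
            "kernelized attention denominator underflowed; "
            "feature map outputs are numerically zero")
    return (pq @ kv_sum) / denom
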