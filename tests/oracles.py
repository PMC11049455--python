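"""Explicit per-node double-loop reference implementations of the layers.

Deliberately slow and literal — these translate the aggregation rules
node by node and are used only to cross-check the vectorised layers.
"""

import numpy as np


def relu(x):
    return np.maximum(x, 0.0)


def gcn_oracle(h, adj, W, normalization="row", self_loops=False,
               activation=True):
    a = np.asarray(adj.todense() if hasattr(adj, "todense") else adj,
                   dtype=float)
    if self_loops:
        a = a + np.eye(a.shape[0])
    deg = a.sum(axis=1)
    n = a.shape[0]
    out = np.zeros((n, W.shape[1]))
    for v in range(n):
        acc = np.zeros(h.shape[1])
        for u in range(n):
            if a[v, u] == 0:
                continue
            if normalization == "row":
                c = deg[v]
            else:
                c = np.sqrt(deg[v] * deg[u])
            acc = acc + h[u] / c
        out[v] = acc @ W
    return relu(out) if activation else out


def sage_oracle(h, adj, W, aggregate="mean", activation=True):
    a = np.asarray(adj.todense() if hasattr(adj, "todense") else adj,
                   dtype=float)
    n = a.shape[0]
    out = np.zeros((n, W.shape[1]))
    for v in range(n):
        nbrs = np.flatnonzero(a[v])
        if nbrs.size == 0:
            agg = np.zeros(h.shape[1])
        elif aggregate == "mean":
            agg = h[nbrs].mean(axis=0)
        else:
            agg = h[nbrs].sum(axis=0)
        out[v] = np.concatenate([h[v], agg]) @ W
    return relu(out) if activation else out


def dense_attention_oracle(z, wq, wk, wv):
    q, k, v = z @ wq, z @ wk, z @ wv
    n = z.shape[0]
    out = np.zeros_like(v)
    for u in range(n):
        scores = np.array([q[u] @ k[j] for j in range(n)])
        scores -= scores.max()
        w = np.exp(scores)
        w /= w.sum()
        for j in range(n):
            out[u] += w[j] * v[j]
    return out
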