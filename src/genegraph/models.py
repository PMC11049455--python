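"""Classifier architectures: parameter initialisation and forward passes.

Four families, mirroring the experiment design this package reproduces:

* ``gcn``         — two graph-convolution layers + MLP head
* ``sage``        — two GraphSAGE layers + MLP head
* ``transformer`` — two all-pair attention layers (dense or kernelized) + head
* ``mlp``         — three dense layers, ignoring the adjacency (the baseline)

All end in a log-softmax over the task's classes.  Weights live in a plain
dict of named Tensors so the optimiser, checkpointing and tests can reach
them directly.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, Optional

import numpy as np

from .autodiff import Tensor
from .layers import (dense_attention_layer, gcn_layer, kernelized_attention_layer,
                     normalize_adjacency, sage_layer)

FAMILIES = ("gcn", "sage", "transformer", "mlp")


@dataclass(frozen=True)
class ModelSpec:
    family: str = "sage"
    hidden_dim: int = 64
    activation: str = "relu"
    gcn_self_loops: bool = True
    gcn_normalization: str = "symmetric"   # or "row" for the literal equation
    sage_aggregate: str = "mean"
    attention: str = "kernelized"          # or "dense"
    phi: str = "positive_rf"
    n_random_features: int = 64
    phi_seed: int = 0

    def __post_init__(self):
        if self.family not in FAMILIES:
            raise ValueError(f"family must be one of {FAMILIES}")
        if self.hidden_dim < 1:
            raise ValueError("hidden_dim must be positive")

    def layer_dims(self, d_in: int, n_classes: int) -> list:
        return [d_in, self.hidden_dim, self.hidden_dim, n_classes]


def _glorot(rng: np.random.Generator, fan_in: int, fan_out: int) -> Tensor:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return Tensor(rng.uniform(-limit, limit, size=(fan_in, fan_out)),
                  requires_grad=True)


def _bias(fan_out: int) -> Tensor:
    return Tensor(np.zeros((1, fan_out)), requires_grad=True)


def init_params(spec: ModelSpec, d_in: int, n_classes: int,
                seed: int = 0) -> Dict[str, Tensor]:
    rng = np.random.default_rng(seed)
    h = spec.hidden_dim
    p: Dict[str, Tensor] = {}
    if spec.family == "gcn":
        p["W1"], p["W2"] = _glorot(rng, d_in, h), _glorot(rng, h, h)
    elif spec.family == "sage":
        p["W1"], p["W2"] = _glorot(rng, 2 * d_in, h), _glorot(rng, 2 * h, h)
    elif spec.family == "transformer":
        # input projection + residual attention blocks (see forward())
        p["W_in"], p["b_in"] = _glorot(rng, d_in, h), _bias(h)
        for layer in ("1", "2"):
            for name in ("Q", "K", "V"):
                p[f"W{name}{layer}"] = _glorot(rng, h, h)
    elif spec.family == "mlp":
        p["W1"], p["W2"] = _glorot(rng, d_in, h), _glorot(rng, h, h)
        p["b1"], p["b2"] = _bias(h), _bias(h)
    p["W_out"], p["b_out"] = _glorot(rng, h, n_classes), _bias(n_classes)
    return p


def forward(spec: ModelSpec, params: Dict[str, Tensor], adjacency,
            X, return_hidden: bool = False):
    """Per-node class log-probabilities (rows log-sum-exp to zero).

    For the ``mlp`` family the adjacency is ignored and ``X`` may be any row
    subset; graph families require ``X`` rows to match the adjacency.
    """
    x = X if isinstance(X, Tensor) else Tensor(np.asarray(X, dtype=np.float64))
    fam = spec.family
    if fam != "mlp" and x.shape[0] != adjacency.shape[0]:
        raise ValueError(
            f"feature rows ({x.shape[0]}) must match adjacency "
            f"({adjacency.shape[0]}) for family {fam!r}")
    if fam == "sage":
        expected_in = params["W1"].shape[0] // 2
    elif fam == "transformer":
        expected_in = params["W_in"].shape[0]
    else:
        expected_in = params["W1"].shape[0]
    if x.shape[1] != expected_in:
        raise ValueError(
            f"feature width {x.shape[1]} does not match model input width "
            f"{expected_in}")

    if fam == "gcn":
        h1 = gcn_layer(x, adjacency, params["W1"], spec.gcn_normalization,
                       spec.gcn_self_loops, activation="relu")
        hidden = gcn_layer(h1, adjacency, params["W2"], spec.gcn_normalization,
                           spec.gcn_self_loops, activation="relu")
    elif fam == "sage":
        h1 = sage_layer(x, adjacency, params["W1"], spec.sage_aggregate,
                        activation="relu")
        hidden = sage_layer(h1, adjacency, params["W2"], spec.sage_aggregate,
                            activation="relu")
    elif fam == "transformer":
        # project into the hidden width, then residual attention blocks:
        # a pure all-pair attention output is a convex mix of value vectors
        # and is nearly node-independent at initialisation, so the residual
        # path is what keeps per-node information flowing
        z = (x @ params["W_in"] + params["b_in"]).relu()
        for layer, phi_off in (("1", 0), ("2", 1)):
            wq, wk, wv = (params[f"WQ{layer}"], params[f"WK{layer}"],
                          params[f"WV{layer}"])
            if spec.attention == "dense":
                att = dense_attention_layer(z, wq, wk, wv)
            else:
                att = kernelized_attention_layer(
                    z, wq, wk, wv, spec.phi, spec.n_random_features,
                    spec.phi_seed + phi_off)
            z = (z + att).relu()
        hidden = z
    elif fam == "mlp":
        h1 = (x @ params["W1"] + params["b1"]).relu()
        hidden = (h1 @ params["W2"] + params["b2"]).relu()
    logits = hidden @ params["W_out"] + params["b_out"]
    logp = logits.log_softmax()
    return (logp, hidden) if return_hidden else logp


# ---------------------------------------------------------------------------
# checkpointing: one .npz of weights plus a JSON sidecar describing the spec
# ---------------------------------------------------------------------------

def save_checkpoint(path, spec: ModelSpec, params: Dict[str, Tensor],
                    meta: Optional[dict] = None) -> None:
    path = Path(path)
    np.savez(path, **{k: v.data for k, v in params.items()})
    sidecar = dict(spec.__dict__)
    sidecar.update(meta or {})
    path.with_suffix(".json").write_text(json.dumps(sidecar, indent=2) + "\n")


def load_checkpoint(path):
    path = Path(path)
    sidecar = json.loads(path.with_suffix(".json").read_text())
    spec_fields = {f for f in ModelSpec.__dataclass_fields__}
    spec = ModelSpec(**{k: v for k, v in sidecar.items() if k in spec_fields})
    with np.load(path if path.suffix == ".npz" else path.with_suffix(".npz")) as z:
        params = {k: Tensor(z[k], requires_grad=True) for k in z.files}
    return spec, params, sidecar
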