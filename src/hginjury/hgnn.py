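"""Hypergraph convolution: node embedding and the HGNN forward pass.

A node embedding layer maps each athlete's feature vector through
``z_i = sigma(W^T x_i + b)``.  A hyperconvolution layer updates vertex ``v``
by averaging, over each hyperedge incident to ``v``, the transformed
embeddings of that hyperedge's members:

    out_v = sigma( sum_{e: v in e} (1/|e|) sum_{u in e} W x_u + b )

i.e. in matrix form ``sigma(Q X W + 1 b^T)`` with the fixed aggregation
operator ``Q_vu = sum_{e contains v and u} 1/|e|``.  Restricting the outer
sum to hyperedges incident to ``v`` is what makes the layer a local message
pass; summing over all hyperedges would give every vertex the same update.
A vertex belonging to no hyperedge receives ``sigma(b)`` (logged warning).
"""

from __future__ import annotations

import logging

import numpy as np

from hginjury.hypergraph import Hypergraph
from hginjury.nn import LayerParams, _act, stack_forward

logger = logging.getLogger(__name__)


def embed_nodes(X: np.ndarray, p: LayerParams) -> np.ndarray:
    """Per-node embedding z_i = sigma(W^T x_i + b); rows of X are nodes."""
    X = np.asarray(X, dtype=float)
    if X.shape[1] != p.weight.shape[0]:
        raise ValueError(
            f"feature dimension {X.shape[1]} != weight rows {p.weight.shape[0]}"
        )
    return _act(X @ p.weight + p.bias, p.activation)


def aggregation_operator(g: Hypergraph) -> np.ndarray:
    """Fixed hyperconvolution operator Q_vu = sum_{e ∋ v,u} 1/|e|  (n x n)."""
    H = g.incidence()
    de = H.sum(axis=0)
    return (H / de) @ H.T


def hyperconv_layer(g: Hypergraph, X_l: np.ndarray, p: LayerParams) -> np.ndarray:
    """One hypergraph convolution layer sigma(Q X W + 1 b^T)."""
    X_l = np.asarray(X_l, dtype=float)
    if X_l.shape[0] != g.n_vertices:
        raise ValueError(f"X has {X_l.shape[0]} rows, hypergraph has {g.n_vertices}")
    H = g.incidence()
    if (H.sum(axis=1) == 0).any():
        isolated = int((H.sum(axis=1) == 0).sum())
        logger.warning(
            "%d vertex/vertices belong to no hyperedge; their output is sigma(b)",
            isolated,
        )
    Q = aggregation_operator(g)
    return _act(Q @ X_l @ p.weight + p.bias, p.activation)


def forward(
    g: Hypergraph, X0: np.ndarray, stack: list[LayerParams]
) -> np.ndarray:
    """Sequential hyperconvolution layers applied to the input features."""
    if not stack:
        logger.warning("empty layer stack; forward pass is the identity")
        return np.asarray(X0, dtype=float)
    X0 = np.asarray(X0, dtype=float)
    if X0.shape[0] != g.n_vertices:
        raise ValueError(f"X0 has {X0.shape[0]} rows, hypergraph has {g.n_vertices}")
    Q = aggregation_operator(g)
    out, _ = stack_forward(X0, stack, prop=Q)
    return out
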