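"""Hypergraph data structure, KNN construction, Laplacians and smoothness.

A hypergraph ``H(V, E, W)`` generalises a graph: each hyperedge connects any
number of vertices, encoding many-to-many interactions (e.g. a whole sparring
group rather than a pair of athletes).  It is represented by a binary
incidence matrix ``H`` of shape |V| x |E| with ``h(v, e) = 1`` iff ``v`` is a
member of ``e``, plus a positive weight per hyperedge.

The vertex-space Laplacian used throughout is the clique-expansion form

    A_ij = sum_e  w_e h(i,e) h(j,e) / delta(e)    (i != j, A_ii = 0)
    L    = D_A - A,   D_A = diag(row sums of A)

where ``delta(e)`` is the hyperedge degree |e|.  ``L`` is symmetric positive
semi-definite, has zero row sums, and reduces to the ordinary graph Laplacian
when every hyperedge has exactly two vertices, which makes the smoothness
quadratic form ``1/2 tr(X^T L X)`` on vertex embeddings well defined.  The
|E| x |E| matrix ``diag(delta) - H^T W H`` is also provided, as a clearly
labelled alternative constructor for auditability; it does not act on vertex
embeddings and is not used by the pipeline.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.spatial.distance import cdist


@dataclass(frozen=True)
class Hypergraph:
    """Hypergraph with ``n_vertices`` vertices and weighted hyperedges.

    ``hyperedges`` is a list of vertex-index tuples (each non-empty, indices
    in ``[0, n_vertices)``); ``weights`` holds one positive weight per
    hyperedge.  Duplicate hyperedges are retained, and degrees count their
    multiplicity.
    """

    n_vertices: int
    hyperedges: tuple[tuple[int, ...], ...]
    weights: tuple[float, ...] = field(default=())

    def __post_init__(self) -> None:
        if self.n_vertices <= 0:
            raise ValueError("n_vertices must be positive")
        edges = tuple(tuple(int(v) for v in e) for e in self.hyperedges)
        object.__setattr__(self, "hyperedges", edges)
        w = self.weights if self.weights else tuple(1.0 for _ in edges)
        w = tuple(float(x) for x in w)
        object.__setattr__(self, "weights", w)
        if len(w) != len(edges):
            raise ValueError("one weight per hyperedge required")
        for e in edges:
            if len(e) == 0:
                raise ValueError("empty hyperedge")
            if len(set(e)) != len(e):
                raise ValueError(f"repeated vertex within hyperedge {e}")
            for v in e:
                if not (0 <= v < self.n_vertices):
                    raise ValueError(f"vertex {v} out of range")
        for x in w:
            if not x > 0:
                raise ValueError("hyperedge weights must be positive")

    @property
    def n_hyperedges(self) -> int:
        return len(self.hyperedges)

    def incidence(self) -> np.ndarray:
        """Binary incidence matrix H of shape (|V|, |E|)."""
        H = np.zeros((self.n_vertices, self.n_hyperedges))
        for j, e in enumerate(self.hyperedges):
            H[list(e), j] = 1.0
        return H

    def to_json(self, path: str | Path | None = None) -> str:
        payload = {
            "n_vertices": self.n_vertices,
            "hyperedges": [list(e) for e in self.hyperedges],
            "weights": list(self.weights),
        }
        text = json.dumps(payload, indent=1)
        if path is not None:
            Path(path).write_text(text)
        return text

    @classmethod
    def from_json(cls, source: str | Path) -> "Hypergraph":
        p = Path(str(source))
        text = p.read_text() if p.exists() else str(source)
        d = json.loads(text)
        return cls(
            n_vertices=int(d["n_vertices"]),
            hyperedges=tuple(tuple(e) for e in d["hyperedges"]),
            weights=tuple(d["weights"]),
        )


@dataclass(frozen=True)
class LaplacianBundle:
    """Vertex-space operators of a hypergraph.

    ``dv``/``de`` are the diagonals of the vertex- and hyperedge-degree
    matrices, ``adjacency`` the clique-expansion adjacency A and ``laplacian``
    the PSD vertex-space Laplacian L = D_A - A.
    """

    dv: np.ndarray
    de: np.ndarray
    adjacency: np.ndarray
    laplacian: np.ndarray


def build_knn_hypergraph(features: np.ndarray, k: int) -> Hypergraph:
    """KNN hypergraph: one hyperedge per vertex, {v} + its k nearest neighbours.

    Distances are Euclidean; ties are broken by lower vertex index so builds
    are deterministic.  All weights are 1.
    """
    X = np.asarray(features, dtype=float)
    if X.ndim != 2:
        raise ValueError("features must be a 2-D matrix")
    if not np.isfinite(X).all():
        raise ValueError("features contain non-finite values")
    n = X.shape[0]
    if k < 1:
        raise ValueError("k must be >= 1")
    if k >= n:
        raise ValueError(f"k={k} requires at least k+1={k + 1} vertices, got {n}")
    D = cdist(X, X)
    idx = np.arange(n)
    edges = []
    for v in range(n):
        d = D[v].copy()
        d[v] = np.inf  # exclude the centroid itself from its neighbour list
        order = np.lexsort((idx, d))  # distance first, index breaks ties
        edges.append((v, *map(int, order[:k])))
    return Hypergraph(n_vertices=n, hyperedges=tuple(edges))


def degrees(g: Hypergraph) -> tuple[np.ndarray, np.ndarray]:
    """Vertex degrees Dv(v) = sum_e w_e h(v,e) and hyperedge degrees De(e) = |e|."""
    H = g.incidence()
    w = np.asarray(g.weights)
    return H @ w, H.sum(axis=0)


def laplacian(g: Hypergraph) -> LaplacianBundle:
    """Clique-expansion adjacency and vertex-space Laplacian (see module docs)."""
    H = g.incidence()
    w = np.asarray(g.weights)
    dv, de = degrees(g)
    A = (H * (w / de)) @ H.T
    np.fill_diagonal(A, 0.0)
    L = np.diag(A.sum(axis=1)) - A
    return LaplacianBundle(dv=dv, de=de, adjacency=A, laplacian=L)


def hyperedge_space_laplacian(g: Hypergraph) -> np.ndarray:
    """Literal |E| x |E| form diag(De) - W^{1/2} H^T H W^{1/2}.

    Provided for auditability only: it lives in hyperedge space, is not PSD
    in general, and cannot act on vertex embeddings, which is why the
    pipeline uses the vertex-space form from :func:`laplacian`.  A product
    H^T W H with the hyperedge-diagonal W is dimensionally impossible, so
    the weights are applied symmetrically on both sides.
    """
    H = g.incidence()
    sqw = np.sqrt(np.asarray(g.weights))
    _, de = degrees(g)
    return np.diag(de) - sqw[:, None] * (H.T @ H) * sqw[None, :]


def smoothness(X: np.ndarray, bundle: LaplacianBundle) -> float:
    """Embedding smoothness 1/2 tr(X^T L X).

    Equals ``1/4 sum_ij A_ij ||X_i - X_j||^2`` over ordered pairs: small when
    vertices sharing hyperedges have similar embeddings, zero for constant
    embeddings.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    L = bundle.laplacian
    if X.shape[0] != L.shape[0]:
        raise ValueError(f"X has {X.shape[0]} rows but L is {L.shape[0]}x{L.shape[0]}")
    return 0.5 * float(np.sum((L @ X) * X))
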