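"""Shared fixtures and brute-force oracles for the test suite."""

from __future__ import annotations

import numpy as np
import pytest

from hginjury.hypergraph import Hypergraph


def random_hypergraph(
    rng: np.random.Generator, max_vertices: int = 8, max_edges: int = 6
) -> Hypergraph:
    """Small random hypergraph (weights in (0.5, 2), every edge non-empty)."""
    n = int(rng.integers(2, max_vertices + 1))
    m = int(rng.integers(1, max_edges + 1))
    edges = []
    for _ in range(m):
        size = int(rng.integers(1, n + 1))
        edges.append(tuple(sorted(rng.choice(n, size=size, replace=False).tolist())))
    weights = tuple(rng.uniform(0.5, 2.0, size=m).tolist())
    return Hypergraph(n_vertices=n, hyperedges=tuple(edges), weights=weights)


def smoothness_pairwise_oracle(X: np.ndarray, A: np.ndarray) -> float:
    """Brute-force 1/4 sum_ij A_ij ||X_i - X_j||^2 over ordered pairs."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] != A.shape[0]:
        X = X.T
    total = 0.0
    n = A.shape[0]
    for i in range(n):
        for j in range(n):
            total += A[i, j] * float(np.sum((X[i] - X[j]) ** 2))
    return 0.25 * total


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
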