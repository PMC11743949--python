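"""Pattern extraction: hyperedge embeddings, reconstruction training, 2-D views.

The pattern pipeline trains an HGNN encoder jointly with an MLP head so
that the MLP reproduces each hyperedge's aggregated embedding
(reconstruction loss ``L = sum_j ||a_j - p_j||^2``).  The encoder is a
dense node-embedding layer ``z_i = sigma(W^T x_i + b)`` followed by
hyperconvolution layers (one by default: repeated neighbourhood averaging
over small interaction groups washes out the within-regime dispersion
structure the visualisation is meant to reveal).  The learned vertex
embeddings are then projected to 2-D (deterministic principal components)
and the compactness of athlete groups is quantified by mean within-group
pairwise distance and silhouette — the quantitative counterpart of "the
MAFT group forms tighter, more organised clusters".

Because the MLP head ends in a sigmoid, reconstruction targets are min-max
scaled to (0, 1) per embedding dimension (scaling constants taken from the
training hyperedges and treated as constants within each gradient step).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from scipy.sparse.csgraph import connected_components
from scipy.spatial.distance import pdist
from sklearn.decomposition import PCA
from sklearn.metrics import silhouette_samples

from hginjury.cohort import AthleteCohort
from hginjury.hgnn import aggregation_operator
from hginjury.hypergraph import Hypergraph, degrees
from hginjury.nn import Adam, LayerParams, init_layer, stack_backward, stack_forward

logger = logging.getLogger(__name__)


@dataclass
class PatternModel:
    """Jointly trained HGNN encoder + MLP reconstruction head.

    ``hgnn_stack[0]`` is a dense node-embedding layer; subsequent layers are
    hyperconvolutions (propagated through the aggregation operator).
    """

    hgnn_stack: list[LayerParams]
    mlp: list[LayerParams]
    aggregation: str = "mean"
    target_min: np.ndarray | None = None
    target_scale: np.ndarray | None = None

    def encoder_props(self, Q: np.ndarray) -> list:
        return [None] + [Q] * (len(self.hgnn_stack) - 1)


@dataclass(frozen=True)
class TrainSettings:
    """Optimisation settings shared by the trainable models.

    Defaults follow the study protocol for pattern analysis: Adam at
    learning rate 0.001, at most 100 epochs, early stopping with patience
    10 on a held-out 20% of hyperedges.
    """

    optimizer: str = "adam"
    learning_rate: float = 1e-3
    max_epochs: int = 100
    patience: int = 10
    validation_fraction: float = 0.2
    seed: int = 0

    def __post_init__(self) -> None:
        if self.optimizer not in ("adam", "sgd"):
            raise ValueError(f"unknown optimizer {self.optimizer!r}")
        if not self.learning_rate > 0:
            raise ValueError("learning_rate must be > 0")
        if self.max_epochs < 1 or self.patience < 0:
            raise ValueError("max_epochs >= 1 and patience >= 0 required")
        if self.patience > self.max_epochs:
            raise ValueError("patience must not exceed max_epochs")
        if not (0.0 < self.validation_fraction < 1.0):
            raise ValueError("validation_fraction must be in (0, 1)")


def aggregate_hyperedge(
    Z: np.ndarray,
    e,
    method: str = "mean",
    weights: np.ndarray | None = None,
) -> np.ndarray:
    """Aggregate the member rows of one hyperedge (mean or weighted mean)."""
    members = list(e)
    if len(members) == 0:
        raise ValueError("cannot aggregate an empty hyperedge")
    rows = np.asarray(Z, dtype=float)[members]
    if method == "mean":
        return rows.mean(axis=0)
    if method == "weighted_mean":
        if weights is None:
            raise ValueError("weighted_mean requires per-vertex weights")
        w = np.asarray(weights, dtype=float)[members]
        if not (w > 0).any():
            raise ValueError("weights must include a positive entry")
        return (w[:, None] * rows).sum(axis=0) / w.sum()
    raise ValueError(f"unknown aggregation {method!r}")


def aggregation_matrix(
    g: Hypergraph, method: str = "mean", weights: np.ndarray | None = None
) -> np.ndarray:
    """Row-stochastic (|E| x |V|) matrix M with a_j = (M Z)_j."""
    H = g.incidence().T  # (m, n)
    if method == "mean":
        return H / H.sum(axis=1, keepdims=True)
    if method == "weighted_mean":
        if weights is None:
            raise ValueError("weighted_mean requires per-vertex weights")
        Hw = H * np.asarray(weights, dtype=float)
        return Hw / Hw.sum(axis=1, keepdims=True)
    raise ValueError(f"unknown aggregation {method!r}")


def reconstruction_loss(A: np.ndarray, P: np.ndarray) -> float:
    """Sum of squared hyperedge reconstruction errors sum_j ||a_j - p_j||^2."""
    A = np.asarray(A, dtype=float)
    P = np.asarray(P, dtype=float)
    if A.shape != P.shape:
        raise ValueError(f"shape mismatch {A.shape} vs {P.shape}")
    return float(np.sum((A - P) ** 2))


def _init_pattern_model(
    d_in: int, rng: np.random.Generator, hgnn_widths: tuple[int, ...]
) -> PatternModel:
    stack: list[LayerParams] = []
    prev = d_in
    for i, w in enumerate(hgnn_widths):
        act = "relu" if i < len(hgnn_widths) - 1 else "identity"
        stack.append(init_layer(rng, prev, w, act))
        prev = w
    d_emb = prev
    mlp = [
        init_layer(rng, d_emb, 64, "relu"),
        init_layer(rng, 64, 32, "relu"),
        init_layer(rng, 32, d_emb, "sigmoid"),
    ]
    return PatternModel(hgnn_stack=stack, mlp=mlp)


def _params_of(model: PatternModel) -> list[np.ndarray]:
    out: list[np.ndarray] = []
    for p in model.hgnn_stack + model.mlp:
        out.extend([p.weight, p.bias])
    return out


def train_pattern_model(
    cohort: AthleteCohort,
    g: Hypergraph,
    settings: TrainSettings = TrainSettings(),
    hgnn_widths: tuple[int, ...] = (64, 32),
) -> tuple[PatternModel, dict[str, list[float]]]:
    """Jointly train the HGNN stack and the MLP head on reconstruction loss.

    Hyperedges are split into training and validation sets (seeded); training
    stops at ``max_epochs`` or when the validation loss has not improved for
    ``patience`` epochs, and the best-validation-epoch parameters are
    restored.  Returns the model and a trace of per-hyperedge mean train /
    validation losses per epoch.
    """
    if g.n_vertices != cohort.n_athletes:
        raise ValueError("hypergraph must be built over the cohort's athletes")
    m = g.n_hyperedges
    rng = np.random.default_rng(settings.seed)
    model = _init_pattern_model(cohort.features.shape[1], rng, hgnn_widths)

    perm = rng.permutation(m)
    n_val = int(round(settings.validation_fraction * m))
    n_val = min(max(n_val, 1 if m > 1 else 0), m - 1)
    val_idx = np.sort(perm[:n_val])
    train_idx = np.sort(perm[n_val:])

    Q = aggregation_operator(g)
    props = model.encoder_props(Q)
    M = aggregation_matrix(g, model.aggregation)
    X0 = cohort.features
    opt = Adam(lr=settings.learning_rate)

    trace: dict[str, list[float]] = {"epoch": [], "train_loss": [], "val_loss": []}
    best_val = np.inf
    best_params = None
    stale = 0

    for epoch in range(settings.max_epochs):
        Z, hg_caches = stack_forward(X0, model.hgnn_stack, prop=props)
        A = M @ Z
        a_tr = A[train_idx]
        col_min = a_tr.min(axis=0)
        scale = 1.0 / (a_tr.max(axis=0) - col_min + 1e-12)
        T = (A - col_min) * scale
        P, mlp_caches = stack_forward(A, model.mlp)

        resid = T - P
        train_loss = float(np.sum(resid[train_idx] ** 2)) / max(len(train_idx), 1)
        val_loss = (
            float(np.sum(resid[val_idx] ** 2)) / len(val_idx)
            if len(val_idx)
            else train_loss
        )
        if not np.isfinite(train_loss) or not np.isfinite(val_loss):
            raise FloatingPointError(
                f"non-finite reconstruction loss at epoch {epoch} "
                f"(train={train_loss}, val={val_loss}); reduce the learning rate"
            )
        trace["epoch"].append(epoch)
        trace["train_loss"].append(train_loss)
        trace["val_loss"].append(val_loss)

        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_params = [p.copy() for p in model.hgnn_stack + model.mlp]
            model.target_min = col_min.copy()
            model.target_scale = scale.copy()
            stale = 0
        else:
            stale += 1
            if stale >= settings.patience:
                break

        # gradient of the mean train loss; validation rows carry no gradient
        G = np.zeros_like(resid)
        G[train_idx] = resid[train_idx] / max(len(train_idx), 1)
        dP = -2.0 * G
        dA_mlp, mlp_grads = stack_backward(dP, mlp_caches, model.mlp)
        dA = dA_mlp + 2.0 * G * scale  # target path: dT = 2G, T linear in A
        dZ = M.T @ dA
        _, hg_grads = stack_backward(dZ, hg_caches, model.hgnn_stack, prop=props)

        flat_grads: list[np.ndarray] = []
        for dw, db in hg_grads + mlp_grads:
            flat_grads.extend([dw, db])
        opt.step(_params_of(model), flat_grads)

    if best_params is not None:
        for tgt, src in zip(model.hgnn_stack + model.mlp, best_params):
            tgt.weight = src.weight
            tgt.bias = src.bias
    return model, trace


def embed_cohort(
    cohort: AthleteCohort, g: Hypergraph, model: PatternModel
) -> np.ndarray:
    """Vertex embeddings under the trained HGNN stack."""
    Q = aggregation_operator(g)
    Z, _ = stack_forward(cohort.features, model.hgnn_stack, prop=model.encoder_props(Q))
    return Z


def project_2d(Z: np.ndarray, method: str = "pca") -> np.ndarray:
    """Deterministic 2-D projection of embeddings (principal components).

    Coordinates are column-centered; component order follows decreasing
    explained variance, and signs are fixed by scikit-learn's deterministic
    SVD sign convention.
    """
    Z = np.asarray(Z, dtype=float)
    if Z.ndim != 2 or Z.shape[0] < 3:
        raise ValueError("need at least 3 rows to project")
    if Z.shape[1] < 2:
        raise ValueError("need at least 2 embedding dimensions")
    if method != "pca":
        raise ValueError(f"unknown projection method {method!r}")
    return PCA(n_components=2, svd_solver="full").fit_transform(Z)


def compactness_stats(coords: np.ndarray, grouping) -> dict:
    """Mean within-group pairwise distance per group plus mean silhouette.

    Groups with fewer than 2 members have no within-group distance and no
    silhouette; they are reported as ``None`` / excluded from the silhouette
    mean rather than silently set to 0.
    """
    coords = np.asarray(coords, dtype=float)
    labels = np.asarray(grouping)
    if coords.shape[0] != labels.shape[0]:
        raise ValueError("one label per row required")
    uniq, counts = np.unique(labels, return_counts=True)
    if len(uniq) < 2:
        raise ValueError("need at least 2 groups")

    within: dict = {}
    for u, c in zip(uniq, counts):
        pts = coords[labels == u]
        within[u if not isinstance(u, np.generic) else u.item()] = (
            float(pdist(pts).mean()) if c >= 2 else None
        )

    valid = np.isin(labels, uniq[counts >= 2])
    silhouette = None
    if valid.sum() >= 2 and len(np.unique(labels[valid])) >= 2:
        # silhouette over samples in non-singleton groups only
        sil = silhouette_samples(coords, labels)
        silhouette = float(sil[valid].mean())
    return {"mean_within_distance": within, "silhouette": silhouette}


def _summarise(g: Hypergraph) -> dict:
    dv, _ = degrees(g)
    n_isolated = int((dv == 0).sum())
    edges = [set(e) for e in g.hyperedges]
    overlaps = [
        len(edges[i] & edges[j])
        for i in range(len(edges))
        for j in range(i + 1, len(edges))
    ]
    mean_overlap = float(np.mean(overlaps)) if overlaps else 0.0
    H = g.incidence()
    A = (H @ H.T) > 0
    np.fill_diagonal(A, False)
    n_comp, _ = connected_components(A, directed=False)
    return {
        "n_isolated_vertices": n_isolated,
        "mean_hyperedge_overlap": mean_overlap,
        "n_components": int(n_comp),
    }


def structure_report(g_pre: Hypergraph, g_post: Hypergraph) -> dict:
    """Structural comparison of two hypergraphs over the same vertices.

    Reports isolated-vertex counts, mean pairwise hyperedge overlap and the
    number of connected components of the clique expansion — the quantities
    behind "more structured and cohesive, with fewer isolated nodes".
    """
    if g_pre.n_vertices != g_post.n_vertices:
        raise ValueError("hypergraphs must share the vertex set")
    return {"pre": _summarise(g_pre), "post": _summarise(g_post)}
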