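"""Graph-Laplacian-regularised hypergraph classifier (rHGNN) and baselines.

The classifier predicts, per athlete, a binary label for each of the nine
injury sites from the 320-dimensional feature vector.  A KNN hypergraph is
built from the features, vertex embeddings X are produced by a two-layer
hyperconvolution stack, and a linear head yields per-site logits.  Training
minimises

    J = CE(logits, y)  +  1/2 tr(X^T L X)  +  lambda * Omega(X)

with CE the per-site binary cross-entropy on labelled vertices, L the
clique-expansion hypergraph Laplacian, and

    Omega(X) = alpha * sum_ij A_ij ||X_i - X_j||^2  +  beta * sum_i ||X_i||^2

the smoothness / weight-decay regulariser (A is the non-negative
clique-expansion adjacency).  Inside the training objective the penalty
block is multiplied by the normalisation

    c(X) = 1 / (n^{3/2} * d * mean(X^2) * mean_degree(A))

(n vertices, d embedding width; ``mean(X^2)`` is treated as a constant
within each gradient step).  Dividing by ``n * d * mean(X^2) * mean_degree``
expresses the smoothness as a scale-free relative roughness of the embedding
cloud, so the penalty neither explodes with embedding magnitude nor
collapses the embeddings to a constant; the extra ``1/sqrt(n)`` makes the
regularisation strength decay relative to the per-sample cross-entropy as
the cohort grows, the usual behaviour of a prior.  The term functions
themselves (:func:`hginjury.hypergraph.smoothness`, :func:`omega`) are
unnormalised.

Training is transductive semi-supervised node classification: the hypergraph
spans all athletes (features only, no label leakage), the cross-entropy is
restricted to the training fold, and held-out vertices are scored from the
same forward pass.  Optimisation is full-batch SGD (momentum 0.9, global
gradient-norm clipping) at learning rate 0.01 with step decay; defaults
lambda=0.2, alpha=0.03, beta=0.005.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.neural_network import MLPClassifier
from sklearn.svm import SVC

from hginjury.cohort import AthleteCohort
from hginjury.hgnn import aggregation_operator
from hginjury.hypergraph import (
    Hypergraph,
    LaplacianBundle,
    build_knn_hypergraph,
    laplacian,
    smoothness,
)
from hginjury.nn import SGD, LayerParams, init_layer, stack_backward, stack_forward
from hginjury.pattern import TrainSettings
from hginjury.stats import ConfusionCounts, metrics

logger = logging.getLogger(__name__)

METRIC_NAMES = ("acc", "ppv", "npv", "sen", "spec")


@dataclass(frozen=True)
class RegularizerConfig:
    """Weights of the regularised objective.

    ``lam`` scales the whole Omega term, ``alpha``/``beta`` weight its
    smoothness and weight-decay parts.  ``include_smoothness`` toggles the
    separate ``1/2 tr(X^T L X)`` term; switching it off together with
    ``lam = 0`` gives the unregularised HGNN classifier.
    """

    lam: float = 0.2
    alpha: float = 0.03
    beta: float = 0.005
    include_smoothness: bool = True

    def __post_init__(self) -> None:
        if self.lam < 0 or self.alpha < 0 or self.beta < 0:
            raise ValueError("regularizer weights must be non-negative")


UNREGULARIZED = RegularizerConfig(lam=0.0, alpha=0.0, beta=0.0, include_smoothness=False)

DEFAULT_CLASSIFIER_SETTINGS = TrainSettings(
    optimizer="sgd", learning_rate=0.01, max_epochs=400, patience=400
)


@dataclass
class ClassifierModel:
    """Fitted rHGNN: hyperconvolution stack, linear head and build settings."""

    hgnn_stack: list[LayerParams]
    head: LayerParams
    knn_k: int
    regularizer: RegularizerConfig
    sites: tuple[str, ...]
    trained_sites: np.ndarray  # boolean, sites with both classes in training


def omega(X: np.ndarray, A: np.ndarray, cfg: RegularizerConfig) -> float:
    """Omega(X) = alpha * sum_{ordered i,j} A_ij ||X_i-X_j||^2 + beta * sum_i ||X_i||^2."""
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    A = np.asarray(A, dtype=float)
    if (A < 0).any():
        raise ValueError("adjacency must be non-negative")
    if A.shape[0] != A.shape[1] or A.shape[0] != X.shape[0]:
        raise ValueError("A must be square with one row per embedding row")
    sq = np.sum(X * X, axis=1)
    deg = A.sum(axis=1)
    # sum_ij A_ij ||Xi-Xj||^2 = sum_ij A_ij (|Xi|^2+|Xj|^2) - 2 tr(X^T A X)
    smooth = float(deg @ sq + A.sum(axis=0) @ sq - 2.0 * np.sum((A @ X) * X))
    smooth = max(smooth, 0.0)  # clip float cancellation noise
    return cfg.alpha * smooth + cfg.beta * float(sq.sum())


def bce_with_logits(
    logits: np.ndarray, y: np.ndarray, mask: np.ndarray | None = None
) -> float:
    """Mean binary cross-entropy over (optionally masked) label entries."""
    logits = np.asarray(logits, dtype=float)
    y = np.asarray(y, dtype=float)
    if logits.shape != y.shape:
        raise ValueError("logits and labels must share a shape")
    per = np.logaddexp(0.0, -np.abs(logits)) + np.maximum(logits, 0.0) - y * logits
    if mask is not None:
        mask = np.asarray(mask, dtype=bool)
        if mask.sum() == 0:
            raise ValueError("mask selects no label entries")
        return float(per[mask].mean())
    return float(per.mean())


def penalty_scale(X: np.ndarray, bundle: LaplacianBundle) -> float:
    """Normalisation c(X) = 1 / (n^{3/2} d mean(X^2) mean_degree(A)).

    Applied to the penalty block of the training objective (see module
    docs); ``mean(X^2)`` is a stop-gradient constant within a step.
    """
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    n, d = X.shape
    rms2 = max(float((X * X).mean()), 1e-12)
    degmean = max(float(np.trace(bundle.laplacian)) / n, 1e-12)
    return 1.0 / (n**1.5 * d * rms2 * degmean)


def total_objective(
    logits: np.ndarray,
    y: np.ndarray,
    X: np.ndarray,
    bundle: LaplacianBundle,
    cfg: RegularizerConfig,
    mask: np.ndarray | None = None,
) -> float:
    """CE + c(X) * (1/2 tr(X^T L X) + lambda * Omega(X))   (see module docs)."""
    if not np.isfinite(logits).all() or not np.isfinite(np.asarray(X)).all():
        raise ValueError("non-finite inputs to the objective")
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X[:, None]
    c = penalty_scale(X, bundle)
    obj = bce_with_logits(logits, y, mask)
    if cfg.include_smoothness:
        obj += c * smoothness(X, bundle)
    obj += c * cfg.lam * omega(X, bundle.adjacency, cfg)
    return obj


def _forward_all(
    features: np.ndarray,
    stack: list[LayerParams],
    head: LayerParams,
    Q: np.ndarray,
):
    X, caches = stack_forward(features, stack, prop=Q)
    head_cache = stack_forward(X, [head])[1][0]
    return X, head_cache.out, caches, head_cache


def train_classifier(
    cohort: AthleteCohort,
    cfg: RegularizerConfig = RegularizerConfig(),
    knn_k: int = 5,
    settings: TrainSettings = DEFAULT_CLASSIFIER_SETTINGS,
    train_mask: np.ndarray | None = None,
    hidden_widths: tuple[int, ...] = (64, 32),
) -> ClassifierModel:
    """Fit the rHGNN on a cohort (transductively if ``train_mask`` is given).

    ``train_mask`` is a boolean vector over athletes; only those vertices
    contribute to the cross-entropy.  Sites with a single class among the
    training vertices are skipped with a warning.
    """
    n, s = cohort.injury_labels.shape
    if train_mask is None:
        train_mask = np.ones(n, dtype=bool)
    train_mask = np.asarray(train_mask, dtype=bool)
    y = cohort.injury_labels.astype(float)

    trained_sites = np.array(
        [len(np.unique(cohort.injury_labels[train_mask, j])) == 2 for j in range(s)]
    )
    if not trained_sites.all():
        skipped = [cohort.sites[j] for j in range(s) if not trained_sites[j]]
        logger.warning("skipping single-class site(s) in training: %s", skipped)
    if not trained_sites.any():
        raise ValueError("no site has both classes among training athletes")

    g = build_knn_hypergraph(cohort.features, knn_k)
    bundle = laplacian(g)
    Q = aggregation_operator(g)
    L = bundle.laplacian

    rng = np.random.default_rng(settings.seed)
    stack: list[LayerParams] = []
    prev = cohort.features.shape[1]
    for i, w in enumerate(hidden_widths):
        act = "relu" if i < len(hidden_widths) - 1 else "identity"
        stack.append(init_layer(rng, prev, w, act))
        prev = w
    head = init_layer(rng, prev, s, "identity")
    head.weight[:] = 0.0  # start at chance logits; avoids saturated sigmoids

    label_mask = train_mask[:, None] & trained_sites[None, :]
    n_terms = label_mask.sum()
    opt = SGD(
        lr=settings.learning_rate, decay_factor=0.5, decay_every=150, momentum=0.9
    )
    max_grad_norm = 5.0  # the aggregation operator is unnormalised; clip for stability

    for epoch in range(settings.max_epochs):
        opt.set_epoch(epoch)
        X, logits, caches, head_cache = _forward_all(cohort.features, stack, head, Q)
        if not np.isfinite(logits).all():
            raise FloatingPointError(f"non-finite logits at epoch {epoch}")

        probs = 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))
        dlogits = np.where(label_mask, probs - y, 0.0) / n_terms
        dX_head, head_grads = stack_backward(dlogits, [head_cache], [head])

        dX = dX_head
        c = penalty_scale(X, bundle)
        if cfg.include_smoothness:
            dX = dX + c * (L @ X)
        if cfg.lam > 0:
            dX = dX + (cfg.lam * c) * (
                4.0 * cfg.alpha * (L @ X) + 2.0 * cfg.beta * X
            )
        _, stack_grads = stack_backward(dX, caches, stack, prop=Q)

        params: list[np.ndarray] = []
        grads: list[np.ndarray] = []
        for p, (dw, db) in zip(stack + [head], stack_grads + head_grads):
            params.extend([p.weight, p.bias])
            grads.extend([dw, db])
        gnorm = np.sqrt(sum(float(np.sum(g * g)) for g in grads))
        if gnorm > max_grad_norm:
            grads = [g * (max_grad_norm / gnorm) for g in grads]
        opt.step(params, grads)

    return ClassifierModel(
        hgnn_stack=stack,
        head=head,
        knn_k=knn_k,
        regularizer=cfg,
        sites=cohort.sites,
        trained_sites=trained_sites,
    )


def predict_proba(model: ClassifierModel, features: np.ndarray) -> np.ndarray:
    """Per-site injury probabilities for all athletes in a feature matrix."""
    g = build_knn_hypergraph(features, model.knn_k)
    Q = aggregation_operator(g)
    X, _ = stack_forward(np.asarray(features, dtype=float), model.hgnn_stack, prop=Q)
    logits, _ = stack_forward(X, [model.head])
    return 1.0 / (1.0 + np.exp(-np.clip(logits, -60, 60)))


def _macro_metrics(y_true: np.ndarray, y_pred: np.ndarray) -> dict[str, float]:
    """Per-site one-vs-rest confusions, macro-averaged; undefined sites skipped."""
    per_metric: dict[str, list[float]] = {m: [] for m in METRIC_NAMES}
    for j in range(y_true.shape[1]):
        t, p = y_true[:, j], y_pred[:, j]
        c = ConfusionCounts(
            tp=int(((t == 1) & (p == 1)).sum()),
            fp=int(((t == 0) & (p == 1)).sum()),
            tn=int(((t == 0) & (p == 0)).sum()),
            fn=int(((t == 1) & (p == 0)).sum()),
        )
        for m, v in metrics(c).items():
            if v is not None:
                per_metric[m].append(v)
    return {m: float(np.mean(v)) if v else np.nan for m, v in per_metric.items()}


def _make_folds(
    cohort: AthleteCohort, folds: int, seed: int
) -> list[tuple[np.ndarray, np.ndarray]]:
    """Stratified folds (by total injury burden); re-drawn (logged) when a
    fold leaves every site single-class in training."""
    n = cohort.n_athletes
    strat = np.minimum(cohort.injury_labels.sum(axis=1), 3)
    for attempt in range(10):
        state = seed + 1000 * attempt
        _, counts = np.unique(strat, return_counts=True)
        if counts.min() >= folds:
            splitter = StratifiedKFold(n_splits=folds, shuffle=True, random_state=state)
            split = splitter.split(np.zeros(n), strat)
        else:
            split = KFold(n_splits=folds, shuffle=True, random_state=state).split(
                np.zeros(n)
            )
        fold_list = [(tr, te) for tr, te in split]
        ok = all(
            any(
                len(np.unique(cohort.injury_labels[tr, j])) == 2
                for j in range(cohort.injury_labels.shape[1])
            )
            for tr, _ in fold_list
        )
        if ok:
            return fold_list
        logger.warning("fold draw %d left a fold without usable sites; re-drawing", attempt)
    return fold_list  # last attempt; degenerate sites are skipped downstream


def _fit_predict_fold(
    cohort: AthleteCohort,
    method: str,
    train_idx: np.ndarray,
    test_idx: np.ndarray,
    cfg: RegularizerConfig,
    knn_k: int,
    settings: TrainSettings,
    seed: int,
) -> np.ndarray:
    y = cohort.injury_labels
    if method in ("rhgnn", "hgnn"):
        mcfg = cfg if method == "rhgnn" else UNREGULARIZED
        mask = np.zeros(cohort.n_athletes, dtype=bool)
        mask[train_idx] = True
        model = train_classifier(
            cohort, mcfg, knn_k, replace(settings, seed=seed), train_mask=mask
        )
        probs = predict_proba(model, cohort.features)
        return (probs[test_idx] > 0.5).astype(int)
    Xtr, ytr = cohort.features[train_idx], y[train_idx]
    Xte = cohort.features[test_idx]
    if method == "mlp":
        clf = MLPClassifier(
            hidden_layer_sizes=(64, 32),
            activation="relu",
            max_iter=400,
            random_state=seed,
        )
        clf.fit(Xtr, ytr)
        pred = np.asarray(clf.predict(Xte))
        if pred.ndim == 1:
            pred = pred[:, None]
        return pred.astype(int)
    if method == "svm":
        preds = []
        for j in range(y.shape[1]):
            if len(np.unique(ytr[:, j])) < 2:
                preds.append(np.full(len(test_idx), int(ytr[0, j])))
                continue
            clf = SVC(kernel="rbf", gamma="scale", random_state=seed)
            clf.fit(Xtr, ytr[:, j])
            preds.append(clf.predict(Xte).astype(int))
        return np.stack(preds, axis=1)
    raise ValueError(f"unknown method {method!r}")


def cross_validate(
    cohort: AthleteCohort,
    method: str = "rhgnn",
    folds: int = 5,
    repeats: int = 1,
    seed: int = 0,
    cfg: RegularizerConfig = RegularizerConfig(),
    knn_k: int = 5,
    settings: TrainSettings = DEFAULT_CLASSIFIER_SETTINGS,
) -> pd.DataFrame:
    """Repeated stratified k-fold evaluation; one row of mean +- std metrics.

    Per fold, per-site one-vs-rest confusions on the held-out athletes are
    macro-averaged into ACC/PPV/NPV/SEN/SPEC; the row reports mean and std
    across ``folds x repeats`` along with ``mean±std`` strings.  Per-fold
    values are available under ``df.attrs["folds"]``.
    """
    if folds < 2:
        raise ValueError("folds must be >= 2")
    fold_rows: list[dict[str, float]] = []
    for r in range(repeats):
        rep_seed = seed + 7919 * r
        for f, (tr, te) in enumerate(_make_folds(cohort, folds, rep_seed)):
            pred = _fit_predict_fold(
                cohort, method, tr, te, cfg, knn_k, settings, rep_seed + f
            )
            fold_rows.append(_macro_metrics(cohort.injury_labels[te], pred))
    return _metric_row(method, fold_rows)


def _metric_row(method: str, fold_rows: list[dict[str, float]]) -> pd.DataFrame:
    row: dict[str, object] = {"method": method}
    for m in METRIC_NAMES:
        vals = np.array([fr[m] for fr in fold_rows], dtype=float)
        vals = vals[np.isfinite(vals)]
        mean = float(vals.mean()) if len(vals) else np.nan
        std = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        row[f"{m}_mean"] = mean
        row[f"{m}_std"] = std
        row[m] = f"{mean:.5f}±{std:.4f}"
    df = pd.DataFrame([row])
    df.attrs["folds"] = fold_rows
    return df


def ablation_grid(
    cohort: AthleteCohort,
    folds: int = 3,
    repeats: int = 1,
    seed: int = 0,
    knn_k: int = 5,
    settings: TrainSettings = DEFAULT_CLASSIFIER_SETTINGS,
) -> pd.DataFrame:
    """Hyperparameter sweep: the full default model plus nine single-parameter
    variations (lambda in {0.01, 0.1, 1.0}, alpha in {0.001, 0.01, 0.1},
    beta in {0.0001, 0.001, 0.01}), each evaluated by cross-validation.

    Row order is deterministic: full model first, then the lambda, alpha and
    beta variations in increasing value.
    """
    base = RegularizerConfig()
    rows = [("rHGNN (full)", base)]
    for lam in (0.01, 0.1, 1.0):
        rows.append((f"λ={lam}", replace(base, lam=lam)))
    for alpha in (0.001, 0.01, 0.1):
        rows.append((f"α={alpha}", replace(base, alpha=alpha)))
    for beta in (0.0001, 0.001, 0.01):
        rows.append((f"β={beta}", replace(base, beta=beta)))

    tables = []
    for name, cfg in rows:
        df = cross_validate(
            cohort, "rhgnn", folds=folds, repeats=repeats, seed=seed, cfg=cfg,
            knn_k=knn_k, settings=settings,
        )
        df["method"] = name
        tables.append(df)
    return pd.concat(tables, ignore_index=True)
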