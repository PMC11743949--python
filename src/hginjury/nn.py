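"""Minimal dense neural-network primitives with explicit gradients.

The models in this package are small (tens to hundreds of vertices, layer
widths <= 64), so layers are plain numpy arrays and backpropagation is
written out by hand.  A layer computes

    Y = sigma(P X W + 1 b^T)

where ``P`` is an optional fixed propagation matrix (the hypergraph
aggregation operator for hyperconvolution layers, identity for dense
layers), ``W``/``b`` are learnable, and ``sigma`` is relu, sigmoid or the
identity.  Initialisation is Glorot-uniform (+-sqrt(6/(d_in+d_out))) from an
explicit seeded generator; there is no global random state anywhere.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

ACTIVATIONS = ("relu", "sigmoid", "identity")


@dataclass
class LayerParams:
    """Learnable parameters of one layer: weight (d_in x d_out), bias (d_out)."""

    weight: np.ndarray
    bias: np.ndarray
    activation: str = "identity"

    def __post_init__(self) -> None:
        self.weight = np.asarray(self.weight, dtype=float)
        self.bias = np.asarray(self.bias, dtype=float)
        if self.weight.ndim != 2 or self.bias.ndim != 1:
            raise ValueError("weight must be 2-D and bias 1-D")
        if self.weight.shape[1] != self.bias.shape[0]:
            raise ValueError("bias length must equal weight column count")
        if self.activation not in ACTIVATIONS:
            raise ValueError(f"unknown activation {self.activation!r}")

    def copy(self) -> "LayerParams":
        return LayerParams(self.weight.copy(), self.bias.copy(), self.activation)


def init_layer(
    rng: np.random.Generator, d_in: int, d_out: int, activation: str = "identity"
) -> LayerParams:
    limit = np.sqrt(6.0 / (d_in + d_out))
    w = rng.uniform(-limit, limit, size=(d_in, d_out))
    return LayerParams(weight=w, bias=np.zeros(d_out), activation=activation)


def _act(z: np.ndarray, name: str) -> np.ndarray:
    if name == "relu":
        return np.maximum(z, 0.0)
    if name == "sigmoid":
        return 1.0 / (1.0 + np.exp(-np.clip(z, -60, 60)))
    return z


def _act_grad(z: np.ndarray, y: np.ndarray, name: str) -> np.ndarray:
    # derivative of sigma at z, expressed via pre-activation z or output y
    if name == "relu":
        return (z > 0).astype(float)
    if name == "sigmoid":
        return y * (1.0 - y)
    return np.ones_like(z)


@dataclass
class LayerCache:
    """Forward-pass intermediates needed by the backward pass."""

    x_in: np.ndarray
    propagated: np.ndarray  # P @ x_in (or x_in when P is None)
    pre: np.ndarray  # propagated @ W + b
    out: np.ndarray


def layer_forward(
    x: np.ndarray, p: LayerParams, prop: np.ndarray | None = None
) -> LayerCache:
    px = x if prop is None else prop @ x
    pre = px @ p.weight + p.bias
    return LayerCache(x_in=x, propagated=px, pre=pre, out=_act(pre, p.activation))


def layer_backward(
    d_out: np.ndarray, cache: LayerCache, p: LayerParams, prop: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Returns (d_x_in, d_weight, d_bias) for upstream gradient ``d_out``."""
    dz = d_out * _act_grad(cache.pre, cache.out, p.activation)
    dw = cache.propagated.T @ dz
    db = dz.sum(axis=0)
    dpx = dz @ p.weight.T
    dx = dpx if prop is None else prop.T @ dpx
    return dx, dw, db


def _per_layer_props(
    stack: list[LayerParams], prop
) -> list[np.ndarray | None]:
    # ``prop`` may be a single matrix shared by every layer, or one per layer
    if isinstance(prop, (list, tuple)):
        if len(prop) != len(stack):
            raise ValueError("one propagation matrix (or None) per layer required")
        return list(prop)
    return [prop] * len(stack)


def stack_forward(
    x: np.ndarray, stack: list[LayerParams], prop=None
) -> tuple[np.ndarray, list[LayerCache]]:
    caches: list[LayerCache] = []
    h = x
    for p, pr in zip(stack, _per_layer_props(stack, prop)):
        c = layer_forward(h, p, pr)
        caches.append(c)
        h = c.out
    return h, caches


def stack_backward(
    d_out: np.ndarray,
    caches: list[LayerCache],
    stack: list[LayerParams],
    prop=None,
) -> tuple[np.ndarray, list[tuple[np.ndarray, np.ndarray]]]:
    """Returns (d_input, [(d_weight, d_bias) per layer, same order as stack])."""
    props = _per_layer_props(stack, prop)
    grads: list[tuple[np.ndarray, np.ndarray]] = [None] * len(stack)  # type: ignore
    d = d_out
    for i in range(len(stack) - 1, -1, -1):
        d, dw, db = layer_backward(d, caches[i], stack[i], props[i])
        grads[i] = (dw, db)
    return d, grads


@dataclass
class Adam:
    """Adam optimiser over a flat list of parameter arrays (updated in place)."""

    lr: float = 1e-3
    beta1: float = 0.9
    beta2: float = 0.999
    eps: float = 1e-8
    _m: list[np.ndarray] = field(default_factory=list)
    _v: list[np.ndarray] = field(default_factory=list)
    _t: int = 0

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        if not self._m:
            self._m = [np.zeros_like(p) for p in params]
            self._v = [np.zeros_like(p) for p in params]
        self._t += 1
        b1t = 1.0 - self.beta1**self._t
        b2t = 1.0 - self.beta2**self._t
        for p, g, m, v in zip(params, grads, self._m, self._v):
            m += (1.0 - self.beta1) * (g - m)
            v += (1.0 - self.beta2) * (g * g - v)
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


@dataclass
class SGD:
    """SGD with heavy-ball momentum and a step learning-rate decay
    (x ``decay_factor`` every ``decay_every`` epochs; epoch must be advanced
    by the caller via :meth:`set_epoch`)."""

    lr: float = 1e-2
    decay_factor: float = 0.5
    decay_every: int = 20
    momentum: float = 0.0
    _epoch: int = 0
    _vel: list[np.ndarray] = field(default_factory=list)

    def set_epoch(self, epoch: int) -> None:
        self._epoch = epoch

    @property
    def current_lr(self) -> float:
        return self.lr * self.decay_factor ** (self._epoch // self.decay_every)

    def step(self, params: list[np.ndarray], grads: list[np.ndarray]) -> None:
        lr = self.current_lr
        if self.momentum == 0.0:
            for p, g in zip(params, grads):
                p -= lr * g
            return
        if not self._vel:
            self._vel = [np.zeros_like(p) for p in params]
        for p, g, v in zip(params, grads, self._vel):
            v *= self.momentum
            v += g
            p -= lr * v
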