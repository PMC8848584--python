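"""Stacked sparse auto-encoder: single-layer training, greedy stacking and
supervised fine-tuning with a softmax head.

Each layer is a sigmoid auto-encoder x → h = f(W⁽¹⁾x + b⁽¹⁾) →
x̂ = f(W⁽²⁾h + b⁽²⁾) trained full-batch on the cost

    J(W, b) = (1/m) Σᵢ ½‖x⁽ⁱ⁾ − x̂⁽ⁱ⁾‖²  +  λ·½‖W‖²  +  β·Σⱼ KL(ρ̂ ‖ ρ̄ⱼ)

where ρ̄ⱼ is the mean activation of hidden unit j over the batch and the
KL term pushes hidden units toward the sparsity target ρ̂.  The stack is
pretrained greedily (the first layer's code is the second layer's input);
the second layer's code is the learned feature handed to the classifier.
Default geometry is 1024 → 1224 → 824 with λ = 0.01 and β = 0.1, trained by
scaled conjugate gradient.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Tuple

import numpy as np

from .optimize import minimize

__all__ = [
    "SAEConfig",
    "SAELayer",
    "sigmoid",
    "encode",
    "decode",
    "sae_cost_and_grad",
    "init_layer",
    "train_sae",
    "stack_pretrain",
    "encode_stack",
]


def sigmoid(z: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-z))


@dataclass
class SAEConfig:
    """Hyper-parameters of the stacked sparse auto-encoder.

    ``layer_sizes`` is (input, hidden1, hidden2); ``l2_weight`` (λ) and
    ``sparsity_weight`` (β) weight the penalties; ``sparsity_target`` (ρ̂)
    is the desired mean hidden activation; epoch counts bound the
    full-batch optimizer iterations; ``finetune_scope`` is ``"head"``
    (softmax only) or ``"top"`` (softmax + second-layer encoder).
    """

    layer_sizes: Tuple[int, int, int] = (1024, 1224, 824)
    l2_weight: float = 0.01
    sparsity_weight: float = 0.1
    sparsity_target: float = 0.05
    unsup_epochs: int = 1000
    sup_epochs: int = 1000
    optimizer: str = "scg"
    finetune_scope: str = "top"
    seed: Optional[int] = None

    def __post_init__(self) -> None:
        if self.l2_weight < 0 or self.sparsity_weight < 0:
            raise ValueError("penalty weights must be >= 0")
        if not (0.0 < self.sparsity_target < 1.0):
            raise ValueError("sparsity_target must lie in (0, 1)")
        if any(s <= 0 for s in self.layer_sizes):
            raise ValueError("layer sizes must be positive")

    def with_sizes(self, sizes: Tuple[int, int, int]) -> "SAEConfig":
        return replace(self, layer_sizes=tuple(sizes))


@dataclass
class SAELayer:
    """One auto-encoder layer: encoder (W1, b1) and decoder (W2, b2)."""

    W1: np.ndarray
    b1: np.ndarray
    W2: np.ndarray
    b2: np.ndarray
    cost_history: List[float] = field(default_factory=list)

    @property
    def n_visible(self) -> int:
        return self.W1.shape[1]

    @property
    def n_hidden(self) -> int:
        return self.W1.shape[0]


def encode(X: np.ndarray, layer: SAELayer) -> np.ndarray:
    X = np.atleast_2d(X)
    if X.shape[1] != layer.n_visible:
        raise ValueError(f"input width {X.shape[1]} != encoder width {layer.n_visible}")
    return sigmoid(X @ layer.W1.T + layer.b1)


def decode(H: np.ndarray, layer: SAELayer) -> np.ndarray:
    H = np.atleast_2d(H)
    if H.shape[1] != layer.n_hidden:
        raise ValueError(f"code width {H.shape[1]} != decoder width {layer.n_hidden}")
    return sigmoid(H @ layer.W2.T + layer.b2)


def _pack(layer: SAELayer) -> np.ndarray:
    return np.concatenate([layer.W1.ravel(), layer.b1, layer.W2.ravel(), layer.b2])


def _unpack(theta: np.ndarray, d: int, h: int) -> SAELayer:
    i = 0
    W1 = theta[i:i + h * d].reshape(h, d); i += h * d
    b1 = theta[i:i + h]; i += h
    W2 = theta[i:i + d * h].reshape(d, h); i += d * h
    b2 = theta[i:i + d]
    return SAELayer(W1=W1, b1=b1, W2=W2, b2=b2)


def sae_cost_and_grad(theta: np.ndarray, X: np.ndarray, d: int, h: int,
                      l2_weight: float, sparsity_weight: float,
                      sparsity_target: float):
    """Cost and flat gradient of the sparse auto-encoder objective."""
    X = np.atleast_2d(X)
    if X.shape[0] == 0:
        raise ValueError("empty batch")
    m = X.shape[0]
    layer = _unpack(theta, d, h)
    A = sigmoid(X @ layer.W1.T + layer.b1)          # (m, h)
    Xhat = sigmoid(A @ layer.W2.T + layer.b2)       # (m, d)

    rho = sparsity_target
    rho_bar = A.mean(axis=0)
    rho_bar_c = np.clip(rho_bar, 1e-10, 1.0 - 1e-10)

    resid = Xhat - X
    J_rec = 0.5 * np.sum(resid**2) / m
    J_w = 0.5 * (np.sum(layer.W1**2) + np.sum(layer.W2**2))
    J_sp = np.sum(rho * np.log(rho / rho_bar_c)
                  + (1.0 - rho) * np.log((1.0 - rho) / (1.0 - rho_bar_c)))
    cost = J_rec + l2_weight * J_w + sparsity_weight * J_sp
    if not np.isfinite(cost):
        raise FloatingPointError("non-finite auto-encoder cost")

    delta_out = resid * Xhat * (1.0 - Xhat) / m     # (m, d)
    gW2 = delta_out.T @ A + l2_weight * layer.W2
    gb2 = delta_out.sum(axis=0)
    sparse_term = sparsity_weight / m * (-rho / rho_bar_c
                                         + (1.0 - rho) / (1.0 - rho_bar_c))
    delta_hid = (delta_out @ layer.W2 + sparse_term) * A * (1.0 - A)
    gW1 = delta_hid.T @ X + l2_weight * layer.W1
    gb1 = delta_hid.sum(axis=0)
    grad = np.concatenate([gW1.ravel(), gb1, gW2.ravel(), gb2])
    return cost, grad


def init_layer(d: int, h: int, rng: np.random.Generator) -> SAELayer:
    """Symmetric uniform initialization scaled by fan-in + fan-out."""
    bound = np.sqrt(6.0 / (d + h))
    W1 = rng.uniform(-bound, bound, size=(h, d))
    W2 = rng.uniform(-bound, bound, size=(d, h))
    return SAELayer(W1=W1, b1=np.zeros(h), W2=W2, b2=np.zeros(d))


def train_sae(X: np.ndarray, n_hidden: int, config: SAEConfig,
              rng: Optional[np.random.Generator] = None) -> SAELayer:
    """Train one sparse auto-encoder layer full-batch.

    The optimizer (SCG by default) only accepts cost-reducing steps, so the
    recorded ``cost_history`` is non-increasing.
    """
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.min() < 0.0 or X.max() > 1.0:
        raise ValueError("auto-encoder inputs must lie in [0, 1]")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    d = X.shape[1]
    layer0 = init_layer(d, n_hidden, rng)

    def fun(theta):
        return sae_cost_and_grad(theta, X, d, n_hidden, config.l2_weight,
                                 config.sparsity_weight, config.sparsity_target)

    res = minimize(fun, _pack(layer0), method=config.optimizer,
                   max_iter=config.unsup_epochs)
    layer = _unpack(res.x, d, n_hidden)
    layer.cost_history = res.cost_history
    return layer


def stack_pretrain(X: np.ndarray, config: SAEConfig,
                   rng: Optional[np.random.Generator] = None
                   ) -> Tuple[SAELayer, SAELayer]:
    """Greedy layer-wise pretraining of the two-layer stack.

    Layer 1 reconstructs the inputs; its hidden activations train layer 2,
    whose code is the learned feature representation.
    """
    d, h1, h2 = config.layer_sizes
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[1] != d:
        raise ValueError(f"input width {X.shape[1]} != configured {d}")
    if rng is None:
        rng = np.random.default_rng(config.seed)
    layer1 = train_sae(X, h1, config, rng=rng)
    H1 = encode(X, layer1)
    layer2 = train_sae(H1, h2, config, rng=rng)
    return layer1, layer2


def encode_stack(X: np.ndarray, layer1: SAELayer, layer2: SAELayer) -> np.ndarray:
    """Code of the stack: second-layer hidden activations."""
    return encode(encode(X, layer1), layer2)
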