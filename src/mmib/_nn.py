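"""Minimal numpy neural-network layer: MLPs with hand-derived gradients.

Parameters live in flat ``{name: ndarray}`` dicts so models can freeze,
clone, and partially fine-tune parameter subsets.  Gradients are accumulated
into a matching dict, which lets a training step combine several forward
passes (e.g. a full-input and a masked-input pass) before one Adam update.
Correctness of the backward passes is checked against finite differences in
the test suite.
"""

from __future__ import annotations

import math

import numpy as np

ParamDict = dict[str, np.ndarray]


def he_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    return rng.standard_normal((fan_in, fan_out)) * math.sqrt(2.0 / fan_in)


class MLP:
    """Fully-connected stack: Linear -> ReLU (-> dropout) repeated, final Linear.

    ``sizes`` = [d_in, h1, ..., d_out]; ReLU (and optional inverted dropout)
    after every layer except the last.
    """

    def __init__(self, prefix: str, sizes: list[int], dropout: float = 0.0):
        self.prefix = prefix
        self.sizes = list(sizes)
        self.dropout = float(dropout)
        self.n_layers = len(sizes) - 1

    def init_params(self, rng: np.random.Generator) -> ParamDict:
        params: ParamDict = {}
        for i in range(self.n_layers):
            params[f"{self.prefix}.W{i}"] = he_init(rng, self.sizes[i], self.sizes[i + 1])
            params[f"{self.prefix}.b{i}"] = np.zeros(self.sizes[i + 1])
        return params

    def param_names(self) -> list[str]:
        out = []
        for i in range(self.n_layers):
            out += [f"{self.prefix}.W{i}", f"{self.prefix}.b{i}"]
        return out

    def forward(
        self,
        x: np.ndarray,
        params: ParamDict,
        train: bool = False,
        rng: np.random.Generator | None = None,
    ) -> tuple[np.ndarray, list]:
        cache = []
        h = x
        for i in range(self.n_layers):
            w, b = params[f"{self.prefix}.W{i}"], params[f"{self.prefix}.b{i}"]
            z = h @ w + b
            if i < self.n_layers - 1:
                a = np.maximum(z, 0.0)
                mask = None
                if train and self.dropout > 0.0:
                    if rng is None:
                        raise ValueError("rng required for dropout in train mode")
                    mask = (rng.random(a.shape) >= self.dropout) / (1.0 - self.dropout)
                    a = a * mask
                cache.append((h, z, mask))
                h = a
            else:
                cache.append((h, z, None))
                h = z
        return h, cache

    def backward(
        self,
        dout: np.ndarray,
        cache: list,
        params: ParamDict,
        grads: ParamDict,
    ) -> np.ndarray:
        """Accumulate parameter gradients into ``grads``; return d(input)."""
        d = dout
        for i in range(self.n_layers - 1, -1, -1):
            h_in, z, mask = cache[i]
            if i < self.n_layers - 1:
                if mask is not None:
                    d = d * mask
                d = d * (z > 0.0)
            w = params[f"{self.prefix}.W{i}"]
            grads[f"{self.prefix}.W{i}"] = grads.get(f"{self.prefix}.W{i}", 0.0) + h_in.T @ d
            grads[f"{self.prefix}.b{i}"] = grads.get(f"{self.prefix}.b{i}", 0.0) + d.sum(axis=0)
            d = d @ w.T
        return d


def softmax(logits: np.ndarray) -> np.ndarray:
    z = logits - logits.max(axis=1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=1, keepdims=True)


def softmax_nll(logits: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray]:
    """Mean negative log-likelihood and gradient wrt logits."""
    p = softmax(logits)
    n = logits.shape[0]
    nll = float(-np.log(np.clip(p[np.arange(n), labels], 1e-300, None)).mean())
    dlogits = p.copy()
    dlogits[np.arange(n), labels] -= 1.0
    return nll, dlogits / n


class Adam:
    """Adam optimizer over a ParamDict, with optional frozen parameters."""

    def __init__(
        self,
        params: ParamDict,
        lr: float = 1e-3,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-8,
        trainable: set[str] | None = None,
    ):
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}
        self.t = 0
        self.trainable = trainable  # None = all

    def step(self, params: ParamDict, grads: ParamDict, lr: float | None = None) -> None:
        self.t += 1
        lr = self.lr if lr is None else lr
        b1c = 1.0 - self.beta1**self.t
        b2c = 1.0 - self.beta2**self.t
        for k in params:
            if self.trainable is not None and k not in self.trainable:
                continue
            g = grads.get(k)
            if g is None:
                continue
            self.m[k] = self.beta1 * self.m[k] + (1 - self.beta1) * g
            self.v[k] = self.beta2 * self.v[k] + (1 - self.beta2) * g * g
            params[k] -= lr * (self.m[k] / b1c) / (np.sqrt(self.v[k] / b2c) + self.eps)


def cosine_lr(base_lr: float, epoch: int, total_epochs: int) -> float:
    """Cosine annealing from base_lr to 0 over the training run."""
    if total_epochs <= 1:
        return base_lr
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * epoch / (total_epochs - 1)))
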