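"""Minimal feed-forward networks with reverse-mode gradients, in NumPy.

Everything the model needs at desk scale: dense layers, ReLU/tanh MLPs,
an Adam optimizer with per-group learning rates and L2 weight decay, and
a few numerically careful scalar maps (softplus, sigmoid, log-softmax).

All arrays are float64 and all randomness flows through an explicit
``numpy.random.Generator``, so full training runs are bit-reproducible
on a single thread.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Parameter",
    "Linear",
    "MLP",
    "Adam",
    "softplus",
    "sigmoid",
    "log_softmax",
    "params_checksum",
]


@dataclass
class Parameter:
    """A trainable array together with its gradient accumulator."""

    value: np.ndarray
    grad: np.ndarray = field(init=False)
    name: str = ""

    def __post_init__(self) -> None:
        self.value = np.asarray(self.value, dtype=np.float64)
        self.grad = np.zeros_like(self.value)

    def zero_grad(self) -> None:
        self.grad[...] = 0.0


def softplus(x: np.ndarray) -> np.ndarray:
    """log(1 + exp(x)), overflow-safe."""
    return np.logaddexp(0.0, x)


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x, dtype=np.float64)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def log_softmax(logits: np.ndarray) -> np.ndarray:
    shifted = logits - logits.max(axis=-1, keepdims=True)
    return shifted - np.log(np.exp(shifted).sum(axis=-1, keepdims=True))


class Linear:
    """Affine layer ``y = x @ W + b`` with He-scaled initialization."""

    def __init__(self, rng: np.random.Generator, n_in: int, n_out: int, name: str = "") -> None:
        w = rng.standard_normal((n_in, n_out)) * np.sqrt(2.0 / n_in)
        self.W = Parameter(w, name=f"{name}.W")
        self.b = Parameter(np.zeros(n_out), name=f"{name}.b")

    def forward(self, x: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        return x @ self.W.value + self.b.value, x

    def backward(self, gy: np.ndarray, cache: np.ndarray, accumulate: bool = True) -> np.ndarray:
        if accumulate:
            self.W.grad += cache.T @ gy
            self.b.grad += gy.sum(axis=0)
        return gy @ self.W.value.T

    def parameters(self) -> list[Parameter]:
        return [self.W, self.b]


_ACTIVATIONS = {
    "relu": (lambda z: np.maximum(z, 0.0), lambda z, g: g * (z > 0)),
    "tanh": (np.tanh, lambda z, g: g * (1.0 - np.tanh(z) ** 2)),
}


class BatchNorm:
    """Per-feature batch normalization with learnable affine and running
    statistics (used at evaluation time)."""

    def __init__(self, n_features: int, momentum: float = 0.1, eps: float = 1e-5, name: str = "") -> None:
        self.gamma = Parameter(np.ones(n_features), name=f"{name}.gamma")
        self.beta = Parameter(np.zeros(n_features), name=f"{name}.beta")
        self.running_mean = np.zeros(n_features)
        self.running_var = np.ones(n_features)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x: np.ndarray, training: bool) -> tuple[np.ndarray, tuple]:
        if training:
            mu = x.mean(axis=0)
            var = x.var(axis=0)
            self.running_mean += self.momentum * (mu - self.running_mean)
            self.running_var += self.momentum * (var - self.running_var)
        else:
            mu, var = self.running_mean, self.running_var
        inv_std = 1.0 / np.sqrt(var + self.eps)
        xhat = (x - mu) * inv_std
        return self.gamma.value * xhat + self.beta.value, (xhat, inv_std, training)

    def backward(self, gy: np.ndarray, cache: tuple, accumulate: bool = True) -> np.ndarray:
        xhat, inv_std, training = cache
        if accumulate:
            self.gamma.grad += np.sum(gy * xhat, axis=0)
            self.beta.grad += gy.sum(axis=0)
        gxhat = gy * self.gamma.value
        if not training:
            return gxhat * inv_std
        return inv_std * (
            gxhat - gxhat.mean(axis=0) - xhat * np.mean(gxhat * xhat, axis=0)
        )

    def parameters(self) -> list[Parameter]:
        return [self.gamma, self.beta]

    def buffers(self) -> list[np.ndarray]:
        return [self.running_mean, self.running_var]


class MLP:
    """Multilayer perceptron; hidden layers are Linear (-> BatchNorm) -> act.

    ``forward`` returns the output and an opaque cache that must be handed
    back to ``backward``; parameter gradients accumulate into ``.grad``
    unless ``accumulate=False`` (used when only the input gradient is
    wanted, e.g. adversarial gradients routed into the encoder).
    ``training=True`` uses batch statistics in the normalization layers and
    updates their running estimates; evaluation mode is deterministic per
    sample.
    """

    def __init__(
        self,
        rng: np.random.Generator,
        sizes: list[int],
        activation: str = "relu",
        batchnorm: bool = False,
        final_activation: str | None = None,
        name: str = "mlp",
    ) -> None:
        if len(sizes) < 2:
            raise ValueError("MLP needs at least input and output sizes")
        self.sizes = list(sizes)
        self.activation = activation
        self._act, self._dact = _ACTIVATIONS[activation]
        self.final_activation = final_activation
        self._fact, self._dfact = (
            _ACTIVATIONS[final_activation] if final_activation else (None, None)
        )
        self.layers = [
            Linear(rng, sizes[i], sizes[i + 1], name=f"{name}.{i}") for i in range(len(sizes) - 1)
        ]
        self.norms = (
            [BatchNorm(sizes[i + 1], name=f"{name}.bn{i}") for i in range(len(sizes) - 2)]
            if batchnorm
            else []
        )

    def forward(self, x: np.ndarray, training: bool = False) -> tuple[np.ndarray, list]:
        x = np.asarray(x, dtype=np.float64)
        caches = []
        h = x
        for i, layer in enumerate(self.layers):
            z, lin_cache = layer.forward(h)
            if i < len(self.layers) - 1:
                bn_cache = None
                if self.norms:
                    z, bn_cache = self.norms[i].forward(z, training)
                caches.append((lin_cache, z, bn_cache))
                h = self._act(z)
            else:
                caches.append((lin_cache, z, None))
                h = self._fact(z) if self._fact else z
        return h, caches

    def __call__(self, x: np.ndarray, training: bool = False) -> np.ndarray:
        return self.forward(x, training=training)[0]

    def backward(self, gy: np.ndarray, caches: list, accumulate: bool = True) -> np.ndarray:
        g = gy
        for i in reversed(range(len(self.layers))):
            lin_cache, z, bn_cache = caches[i]
            if i == len(self.layers) - 1 and self._dfact:
                g = self._dfact(z, g)
            if i < len(self.layers) - 1:
                g = self._dact(z, g)
                if self.norms:
                    g = self.norms[i].backward(g, bn_cache, accumulate=accumulate)
            g = self.layers[i].backward(g, lin_cache, accumulate=accumulate)
        return g

    def parameters(self) -> list[Parameter]:
        params = [p for layer in self.layers for p in layer.parameters()]
        params.extend(p for norm in self.norms for p in norm.parameters())
        return params

    def buffers(self) -> list[np.ndarray]:
        return [b for norm in self.norms for b in norm.buffers()]


class Adam:
    """Adam with classic (coupled) L2 weight decay, one group of parameters."""

    def __init__(
        self,
        params: list[Parameter],
        lr: float = 1e-3,
        weight_decay: float = 0.0,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ) -> None:
        self.params = params
        self.lr = float(lr)
        self.weight_decay = float(weight_decay)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.value) for p in params]
        self.v = [np.zeros_like(p.value) for p in params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.zero_grad()

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for p, m, v in zip(self.params, self.m, self.v):
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.value
            m *= self.b1
            m += (1.0 - self.b1) * g
            v *= self.b2
            v += (1.0 - self.b2) * g * g
            p.value -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def params_checksum(params: list[Parameter]) -> float:
    """Order-dependent digest of parameter values; changes iff any value does."""
    h = 0.0
    for i, p in enumerate(params):
        h += float(np.sum(p.value * np.cos(0.1 * i + np.arange(p.value.size).reshape(p.value.shape) % 97)))
    return h
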