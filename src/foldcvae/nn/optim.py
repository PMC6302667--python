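"""First-order optimisers: RMSprop (default), Adam, Adamax, Adagrad.

Each keeps one slot dictionary per (layer index, parameter name) so a
single optimiser instance can drive a whole layer stack. Update rules are
the standard textbook forms; slot arrays are float32 like the weights.
"""

from __future__ import annotations

import numpy as np

from ..errors import ConfigurationError

__all__ = ["make_optimizer", "Optimizer", "OPTIMIZERS"]


class Optimizer:
    def __init__(self, lr: float):
        if lr <= 0:
            raise ConfigurationError(f"learning rate must be positive, got {lr}")
        self.lr = lr
        self.slots: dict = {}
        self.t = 0

    def step(self, layers) -> None:
        self.t += 1
        for li, layer in enumerate(layers):
            for name, p in layer.params.items():
                g = layer.grads[name].astype(p.dtype, copy=False)
                self._update((li, name), p, g)

    def _update(self, key, p, g):  # pragma: no cover
        raise NotImplementedError


class RMSprop(Optimizer):
    def __init__(self, lr=1e-3, rho=0.9, eps=1e-7):
        super().__init__(lr)
        self.rho, self.eps = rho, eps

    def _update(self, key, p, g):
        v = self.slots.setdefault(key, np.zeros_like(p))
        v *= self.rho
        v += (1 - self.rho) * g * g
        p -= self.lr * g / (np.sqrt(v) + self.eps)


class Adam(Optimizer):
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, key, p, g):
        m, v = self.slots.setdefault(key, (np.zeros_like(p), np.zeros_like(p)))
        m *= self.beta1
        m += (1 - self.beta1) * g
        v *= self.beta2
        v += (1 - self.beta2) * g * g
        mhat = m / (1 - self.beta1 ** self.t)
        vhat = v / (1 - self.beta2 ** self.t)
        p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


class Adamax(Optimizer):
    def __init__(self, lr=1e-3, beta1=0.9, beta2=0.999, eps=1e-7):
        super().__init__(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps

    def _update(self, key, p, g):
        m, u = self.slots.setdefault(key, (np.zeros_like(p), np.zeros_like(p)))
        m *= self.beta1
        m += (1 - self.beta1) * g
        np.maximum(self.beta2 * u, np.abs(g), out=u)
        p -= self.lr * m / ((1 - self.beta1 ** self.t) * (u + self.eps))


class Adagrad(Optimizer):
    def __init__(self, lr=1e-2, eps=1e-7):
        super().__init__(lr)
        self.eps = eps

    def _update(self, key, p, g):
        v = self.slots.setdefault(key, np.zeros_like(p))
        v += g * g
        p -= self.lr * g / (np.sqrt(v) + self.eps)


OPTIMIZERS = {
    "rmsprop": RMSprop,
    "adam": Adam,
    "adamax": Adamax,
    "adagrad": Adagrad,
}


def make_optimizer(name: str, lr: float | None = None) -> Optimizer:
    key = name.lower()
    if key not in OPTIMIZERS:
        raise ConfigurationError(
            f"unknown optimizer {name!r}; choose from {sorted(OPTIMIZERS)}")
    cls = OPTIMIZERS[key]
    return cls() if lr is None else cls(lr=lr)
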