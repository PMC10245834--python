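"""Adam and a reduce-on-plateau learning-rate schedule for the NumPy models."""

from __future__ import annotations

import numpy as np


class Adam:
    """Adam over a dict of named parameter arrays (updates in place)."""

    def __init__(self, params: dict[str, np.ndarray], lr: float,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0, decay_exclude: tuple[str, ...] = ()):
        self.params = params
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.decay_exclude = decay_exclude
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for k, g in grads.items():
            m = self.m[k]
            v = self.v[k]
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            self.params[k] -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
            # decoupled weight decay (AdamW style)
            if self.weight_decay and not k.startswith(self.decay_exclude or ("\x00",)):
                self.params[k] -= self.lr * self.weight_decay * self.params[k]


class ReduceLROnPlateau:
    """Multiply the optimizer lr by ``factor`` after ``patience`` consecutive
    epochs without improvement of the (maximized) validation metric."""

    def __init__(self, optimizer: Adam, factor: float = 0.5, patience: int = 5,
                 threshold: float = 1e-8):
        self.opt = optimizer
        self.factor = factor
        self.patience = patience
        self.threshold = threshold
        self.best = -np.inf
        self.num_bad = 0

    def step(self, metric: float) -> float:
        """Record one epoch's metric; return the (possibly reduced) lr."""
        if metric > self.best + self.threshold:
            self.best = metric
            self.num_bad = 0
        else:
            self.num_bad += 1
            if self.num_bad >= self.patience:
                self.opt.lr *= self.factor
                self.num_bad = 0
        return self.opt.lr
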