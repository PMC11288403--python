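"""Adam optimizer and a reduce-on-plateau learning-rate scheduler."""

from __future__ import annotations

import numpy as np

from .modules import Parameter

__all__ = ["Adam", "ReduceLROnPlateau"]


class Adam:
    def __init__(self, params, lr: float = 1e-3, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params: list[Parameter] = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if not p.requires_grad or p.grad is None:
                continue
            g = p.grad
            self._m[i] = self.b1 * self._m[i] + (1 - self.b1) * g
            self._v[i] = self.b2 * self._v[i] + (1 - self.b2) * g * g
            mhat = self._m[i] / (1 - self.b1 ** self.t)
            vhat = self._v[i] / (1 - self.b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "lr": self.lr,
                "m": [m.copy() for m in self._m],
                "v": [v.copy() for v in self._v]}

    def load_state_dict(self, state: dict):
        self.t = state["t"]
        self.lr = state["lr"]
        self._m = [np.asarray(m).copy() for m in state["m"]]
        self._v = [np.asarray(v).copy() for v in state["v"]]


class ReduceLROnPlateau:
    """Multiply the learning rate of the attached optimizers by `factor`
    after `patience` consecutive epochs without improvement of the
    monitored quantity (lower is better)."""

    def __init__(self, optimizers, patience: int = 20, factor: float = 0.1,
                 min_delta: float = 0.0):
        self.optimizers = list(optimizers)
        self.patience = patience
        self.factor = factor
        self.min_delta = min_delta
        self.best = np.inf
        self.num_bad = 0

    def step(self, metric: float) -> bool:
        """Returns True if a reduction was applied at this call."""
        if metric < self.best - self.min_delta:
            self.best = metric
            self.num_bad = 0
            return False
        self.num_bad += 1
        if self.num_bad >= self.patience:
            for opt in self.optimizers:
                opt.lr *= self.factor
            self.num_bad = 0
            return True
        return False
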