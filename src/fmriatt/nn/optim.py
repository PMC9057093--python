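"""Adam and a reduce-on-plateau learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .core import Parameter


class Adam:
    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]
        self._v = [np.zeros_like(p.data, dtype=np.float64) for p in self.params]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        c1 = 1.0 - b1**self.t
        c2 = 1.0 - b2**self.t
        for p, m, v in zip(self.params, self._m, self._v):
            if not p.trainable or p.grad is None:
                continue
            g = p.grad.astype(np.float64)
            m += (1 - b1) * (g - m)
            v += (1 - b2) * (g * g - v)
            upd = (
                self.lr * getattr(p, "lr_scale", 1.0)
                * (m / c1) / (np.sqrt(v / c2) + self.eps)
            )
            p.data = (p.data.astype(np.float64) - upd).astype(p.data.dtype)


class ReduceLROnPlateau:
    """Divide the learning rate by `factor` after `patience` epochs without a
    relative validation-loss improvement of at least `rel_threshold`."""

    def __init__(self, optimizer: Adam, factor: float = 5.0, patience: int = 15,
                 rel_threshold: float = 1e-4):
        if factor <= 1:
            raise ValueError("decay factor must exceed 1")
        self.optimizer = optimizer
        self.factor = factor
        self.patience = patience
        self.rel_threshold = rel_threshold
        self.best = np.inf
        self.stale = 0
        self.events: list[int] = []  # epoch indices at which lr was reduced
        self.n_reductions = 0
        self._lr0 = optimizer.lr

    def step(self, val_loss: float, epoch: int) -> bool:
        if val_loss < self.best * (1.0 - self.rel_threshold):
            self.best = val_loss
            self.stale = 0
            return False
        self.stale += 1
        if self.stale >= self.patience:
            self.n_reductions += 1
            # recomputed from the base rate so lr == lr0 / factor**r exactly
            self.optimizer.lr = self._lr0 / self.factor**self.n_reductions
            self.events.append(epoch)
            self.stale = 0
            return True
        return False
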