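"""AdamW optimiser and the warmup + cosine learning-rate schedule."""

from __future__ import annotations

import math

import numpy as np

from .layers import Parameter


class AdamW:
    """Adam with decoupled weight decay.

    Decay is applied only to parameters flagged ``decay=True`` (weight
    matrices), never to biases, layer-norm gains or embeddings.
    """

    def __init__(self, params: list[Parameter], lr: float = 1e-3,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.05):
        self.params = list(params)
        self.lr = lr
        self.betas = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self._m = [np.zeros_like(p.value) for p in self.params]
        self._v = [np.zeros_like(p.value) for p in self.params]
        self._t = 0

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self._t += 1
        b1, b2 = self.betas
        bc1 = 1.0 - b1 ** self._t
        bc2 = 1.0 - b2 ** self._t
        for p, m, v in zip(self.params, self._m, self._v):
            g = p.grad
            m *= b1
            m += (1.0 - b1) * g
            v *= b2
            v += (1.0 - b2) * g * g
            update = (m / bc1) / (np.sqrt(v / bc2) + self.eps)
            if p.decay and self.weight_decay:
                update = update + self.weight_decay * p.value
            p.value -= self.lr * update


def warmup_cosine_lr(epoch: int, base_lr: float, warmup_epochs: int, total_epochs: int) -> float:
    """Linear warmup to ``base_lr`` then cosine annealing to zero."""
    if epoch < warmup_epochs:
        return base_lr * (epoch + 1) / warmup_epochs
    span = max(total_epochs - warmup_epochs, 1)
    progress = (epoch - warmup_epochs) / span
    return base_lr * 0.5 * (1.0 + math.cos(math.pi * progress))
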