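"""Adam optimizer and the cosine learning-rate schedule."""

from __future__ import annotations

import numpy as np

from .layers import Parameter


class Adam:
    """Adam with classic L2 weight decay (decay added to the gradient)."""

    def __init__(self, params: list[Parameter], lr: float = 5e-4,
                 betas: tuple[float, float] = (0.9, 0.999), eps: float = 1e-8,
                 weight_decay: float = 0.0):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1t = 1.0 - self.b1 ** self.t
        b2t = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def cosine_lr(epoch: int, base_lr: float = 5e-4, T: int = 80,
              floor: float = 1e-6) -> float:
    """Cosine-annealed learning rate: ``base_lr * (1 + cos(pi*e/T)) / 2``.

    Epochs past ``T`` hold the terminal value; a small floor keeps late
    epochs active (the raw cosine reaches exactly 0 at ``T``).
    """
    e = min(epoch, T)
    lr = base_lr * 0.5 * (1.0 + np.cos(np.pi * e / T))
    return max(lr, floor)
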