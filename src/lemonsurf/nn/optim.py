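"""AdamW with decoupled weight decay and a linear learning-rate ramp-down."""

from __future__ import annotations

import numpy as np


class AdamW:
    """Decoupled-weight-decay Adam.

    ``momentum`` maps onto beta1 (the usual reading of "momentum" for an
    Adam-family optimizer); beta2 is fixed at 0.999.  Decay is applied only
    to parameter groups flagged ``decay=True`` (convolution kernels); norm
    scales and biases are excluded, the standard practice for detectors.
    """

    def __init__(self, param_groups, lr=0.001667, momentum=0.9,
                 weight_decay=0.0005, eps=1e-8):
        # param_groups: list of dicts {"params": [...], "decay": bool}
        self.groups = param_groups
        self.lr = lr
        self.beta1 = momentum
        self.beta2 = 0.999
        self.wd = weight_decay
        self.eps = eps
        self.t = 0
        self._m = {}
        self._v = {}

    def step(self):
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1 - b1 ** self.t
        bc2 = 1 - b2 ** self.t
        for group in self.groups:
            decay = self.wd if group.get("decay", False) else 0.0
            for p in group["params"]:
                if p.grad is None:
                    continue
                k = id(p)
                if k not in self._m:
                    self._m[k] = np.zeros_like(p.data)
                    self._v[k] = np.zeros_like(p.data)
                m, v = self._m[k], self._v[k]
                g = p.grad
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                if decay:
                    p.data *= 1.0 - self.lr * decay
                p.data -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)

    def zero_grad(self):
        for group in self.groups:
            for p in group["params"]:
                p.grad = None


def linear_lr(lr0: float, step: int, total_steps: int, final_frac: float = 0.01) -> float:
    """Linear decay from lr0 to final_frac*lr0 over the run."""
    if total_steps <= 1:
        return lr0
    frac = min(step / (total_steps - 1), 1.0)
    return lr0 * (1.0 - frac * (1.0 - final_frac))


def param_groups_for(model):
    """Split a model's parameters into decayed (conv kernels) and not."""
    decay, no_decay = [], []
    for name, p in model.named_parameters():
        (decay if p.data.ndim >= 2 else no_decay).append(p)
    return [{"params": decay, "decay": True},
            {"params": no_decay, "decay": False}]
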