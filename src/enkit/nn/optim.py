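"""Adam optimiser (default betas/epsilon as in the original formulation)."""

from __future__ import annotations

import numpy as np

from .network import Network


class Adam:
    def __init__(self, net: Network, lr: float = 0.001, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[tuple[int, str], np.ndarray] = {}
        self.v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, layer in enumerate(self.net.layers):
            for key, p in layer.params.items():
                g = layer.grads[key]
                slot = (i, key)
                m = self.m.setdefault(slot, np.zeros_like(p))
                v = self.v.setdefault(slot, np.zeros_like(p))
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
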