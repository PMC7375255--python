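"""Adam optimiser over the parameter dicts of a list of layers."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, layers, lr: float = 1e-6, beta1: float = 0.9,
                 beta2: float = 0.999, eps: float = 1e-8) -> None:
        self.layers = [ly for ly in layers if ly.params]
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self.m = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]
        self.v = [{k: np.zeros_like(v) for k, v in ly.params.items()} for ly in self.layers]

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bc1 = 1.0 - b1 ** self.t
        bc2 = 1.0 - b2 ** self.t
        for i, ly in enumerate(self.layers):
            for k, p in ly.params.items():
                g = ly.grads[k]
                m = self.m[i][k]
                v = self.v[i][k]
                m *= b1
                m += (1 - b1) * g
                v *= b2
                v += (1 - b2) * g * g
                p -= self.lr * (m / bc1) / (np.sqrt(v / bc2) + self.eps)
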