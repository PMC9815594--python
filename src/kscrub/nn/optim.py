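"""Adam optimizer over the (layer, name, array) parameter iterable."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, net, lr: float = 1e-3, beta1: float = 0.9, beta2: float = 0.999,
                 eps: float = 1e-8):
        self.net = net
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.t = 0
        self._m: dict[tuple[int, str], np.ndarray] = {}
        self._v: dict[tuple[int, str], np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for layer, name, arr in self.net.parameters():
            g = layer.grads.get(name)
            if g is None:
                continue
            key = (id(layer), name)
            m = self._m.setdefault(key, np.zeros_like(arr))
            v = self._v.setdefault(key, np.zeros_like(arr))
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * g * g
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            arr -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
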