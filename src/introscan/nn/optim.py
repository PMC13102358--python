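"""Adam optimizer over the flat parameter registry of a network."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(self, learning_rate=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.lr = learning_rate
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[str, np.ndarray] = {}
        self._v: dict[str, np.ndarray] = {}

    def step(self, named_params) -> None:
        """``named_params``: iterable of (name, param array, grad array)."""
        self.t += 1
        b1t = 1 - self.b1**self.t
        b2t = 1 - self.b2**self.t
        for name, p, g in named_params:
            m = self._m.setdefault(name, np.zeros_like(p))
            v = self._v.setdefault(name, np.zeros_like(p))
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)
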