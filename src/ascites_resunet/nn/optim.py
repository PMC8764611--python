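"""Adam optimizer over a network's named parameters."""

from __future__ import annotations

import numpy as np


class Adam:
    def __init__(
        self,
        net,
        lr: float = 1e-4,
        beta1: float = 0.9,
        beta2: float = 0.999,
        eps: float = 1e-7,
    ):
        self.net = net
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.t = 0
        self.m: dict[str, np.ndarray] = {}
        self.v: dict[str, np.ndarray] = {}
        for name, arr, _ in net.named_params():
            self.m[name] = np.zeros_like(arr, dtype=np.float32)
            self.v[name] = np.zeros_like(arr, dtype=np.float32)

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, arr, grad_fn in self.net.named_params():
            g = grad_fn()
            if g is None:
                raise RuntimeError(f"no gradient for parameter {name}")
            m = self.m[name]
            v = self.v[name]
            m *= b1
            m += (1 - b1) * g
            v *= b2
            v += (1 - b2) * np.square(g)
            arr -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
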