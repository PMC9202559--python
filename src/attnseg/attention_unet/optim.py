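"""Adam optimizer over named Parameter lists."""

from __future__ import annotations

import numpy as np

from attnseg.attention_unet.layers import Parameter


class Adam:
    def __init__(
        self,
        params: list[tuple[str, Parameter]],
        lr: float = 1e-4,
        betas: tuple[float, float] = (0.9, 0.999),
        eps: float = 1e-8,
    ):
        self.params = list(params)
        self.lr = lr
        self.beta1, self.beta2 = betas
        self.eps = eps
        self.t = 0
        self._m = {name: np.zeros_like(p.value) for name, p in self.params}
        self._v = {name: np.zeros_like(p.value) for name, p in self.params}

    def zero_grad(self) -> None:
        for _, p in self.params:
            p.grad[...] = 0.0

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        bias1 = 1.0 - b1**self.t
        bias2 = 1.0 - b2**self.t
        for name, p in self.params:
            m = self._m[name]
            v = self._v[name]
            m *= b1
            m += (1 - b1) * p.grad
            v *= b2
            v += (1 - b2) * p.grad * p.grad
            p.value -= self.lr * (m / bias1) / (np.sqrt(v / bias2) + self.eps)
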