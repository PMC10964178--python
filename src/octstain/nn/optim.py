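"""Adaptive moment estimation (Adam) with serialisable state."""

from __future__ import annotations

import numpy as np

from .layers import Parameter

__all__ = ["Adam"]


class Adam:
    """Adam with the GAN-customary betas (0.5, 0.999) as default."""

    def __init__(self, params: list[Parameter], lr: float = 1e-4,
                 betas: tuple[float, float] = (0.5, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        bc1 = 1.0 - self.b1 ** self.t
        bc2 = 1.0 - self.b2 ** self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1.0 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1.0 - self.b2) * (g * g)
            mhat = self.m[i] / bc1
            vhat = self.v[i] / bc2
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)

    # -- checkpoint support --------------------------------------------------

    def state_arrays(self, prefix: str) -> dict[str, np.ndarray]:
        out: dict[str, np.ndarray] = {f"{prefix}.t": np.array([self.t], dtype=np.int64)}
        for i, (m, v) in enumerate(zip(self.m, self.v)):
            out[f"{prefix}.m.{i}"] = m
            out[f"{prefix}.v.{i}"] = v
        return out

    def load_state_arrays(self, state: dict[str, np.ndarray], prefix: str) -> None:
        self.t = int(state[f"{prefix}.t"][0])
        for i in range(len(self.params)):
            self.m[i] = np.asarray(state[f"{prefix}.m.{i}"], dtype=np.float32).copy()
            self.v[i] = np.asarray(state[f"{prefix}.v.{i}"], dtype=np.float32).copy()
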