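"""Small dense neural-network primitives (NumPy, explicit backprop).

The surrogate models only need width-32 ReLU MLPs, so forward/backward
passes are written out explicitly and trained with a hand-rolled Adam.
Everything is seeded through ``numpy.random.Generator`` for bit-stable
reruns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["MLP", "MLPGrads", "Adam", "step_lr"]


class MLP:
    """Fully connected ReLU network; the output layer is linear.

    ``dims = [in, h1, ..., out]``.  He-initialized weights; ``zero_output``
    zeroes the final layer (used for identity-passthrough initializations
    and the boundary-value diagnostics of the decoder).
    """

    def __init__(self, dims: list[int], rng: np.random.Generator,
                 zero_output: bool = False):
        self.dims = list(dims)
        self.W: list[np.ndarray] = []
        self.b: list[np.ndarray] = []
        for a, b_ in zip(dims[:-1], dims[1:]):
            self.W.append(rng.normal(0.0, np.sqrt(2.0 / a), size=(a, b_)))
            self.b.append(np.zeros(b_))
        if zero_output:
            self.W[-1][:] = 0.0
            self.b[-1][:] = 0.0

    @property
    def n_layers(self) -> int:
        return len(self.W)

    def forward(self, x: np.ndarray, cache: list | None = None) -> np.ndarray:
        """Forward pass; if ``cache`` is a list, layer inputs are appended to
        it for use in :meth:`backward`."""
        h = x
        for k in range(self.n_layers):
            if cache is not None:
                cache.append(h)
            h = h @ self.W[k] + self.b[k]
            if k < self.n_layers - 1:
                h = np.maximum(h, 0.0)
        return h

    def backward(self, dout: np.ndarray, cache: list,
                 grads: "MLPGrads") -> np.ndarray:
        """Backprop ``dout`` (dL/doutput); accumulates parameter gradients
        into ``grads`` and returns dL/dinput."""
        d = dout
        for k in range(self.n_layers - 1, -1, -1):
            x = cache[k]
            if k < self.n_layers - 1:
                # cache[k+1] is the ReLU output of layer k, so its positive
                # entries mark active units
                d = d * (cache[k + 1] > 0)
            grads.dW[k] += x.T @ d
            grads.db[k] += d.sum(axis=0)
            d = d @ self.W[k].T
        return d

    def params(self):
        return self.W + self.b

    def state_dict(self) -> dict:
        return {"dims": self.dims,
                "W": [w.copy() for w in self.W],
                "b": [b.copy() for b in self.b]}

    @classmethod
    def from_state(cls, state: dict) -> "MLP":
        m = cls.__new__(cls)
        m.dims = list(state["dims"])
        m.W = [np.array(w, dtype=np.float64) for w in state["W"]]
        m.b = [np.array(b, dtype=np.float64) for b in state["b"]]
        return m


class MLPGrads:
    """Gradient accumulator matching one MLP's parameters."""

    def __init__(self, mlp: MLP):
        self.dW = [np.zeros_like(w) for w in mlp.W]
        self.db = [np.zeros_like(b) for b in mlp.b]

    def zero(self) -> None:
        for g in self.dW + self.db:
            g[:] = 0.0

    def scale(self, s: float) -> None:
        for g in self.dW + self.db:
            g *= s

    def flat(self):
        return self.dW + self.db


class Adam:
    """Adam optimizer over a flat list of parameter arrays."""

    def __init__(self, params: list[np.ndarray], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.m = [np.zeros_like(p) for p in params]
        self.v = [np.zeros_like(p) for p in params]
        self.t = 0

    def step(self, grads: list[np.ndarray]) -> None:
        self.t += 1
        b1t = 1 - self.b1 ** self.t
        b2t = 1 - self.b2 ** self.t
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            p -= self.lr * (m / b1t) / (np.sqrt(v / b2t) + self.eps)


def step_lr(epoch: int, n_epochs: int, lr_max: float = 1e-3,
            lr_min: float = 1e-6) -> float:
    """Step learning-rate decay spanning [lr_max, lr_min] in decade drops at
    25/50/75% of the epoch budget (1e-3 → 1e-4 → 1e-5 → 1e-6 by default)."""
    frac = epoch / max(n_epochs, 1)
    n_drops = int(np.floor(np.log10(lr_max / lr_min) + 0.5))
    k = min(n_drops, int(frac * (n_drops + 1)))
    return lr_max * 10.0 ** (-k)
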