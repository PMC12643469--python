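"""Neural-network building blocks over the autodiff core.

Provides exactly the layers the estimation network uses: dense layers, layer
normalization, a gated recurrent unit, leaky-rectifier activation and an
Adam optimizer.  Initialization is seeded and reproducible.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import (
    Tensor,
    concatenate,
    matmul,
    maximum_const,
    sigmoid,
    sqrt,
    tanh,
    tmean,
    tsum,
    broadcast_to,
)

__all__ = ["Parameter", "Module", "Linear", "LayerNorm", "GRU", "leaky_relu", "Adam"]


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(np.asarray(data, dtype=np.float64), requires_grad=True)


class Module:
    """Minimal container with recursive parameter collection."""

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        out.append(item)
        return out

    def state_dict(self):
        return [p.data.copy() for p in self.parameters()]

    def load_state_dict(self, arrays):
        params = self.parameters()
        if len(arrays) != len(params):
            raise ValueError(
                f"state mismatch: {len(arrays)} arrays for {len(params)} parameters"
            )
        for p, a in zip(params, arrays):
            if p.data.shape != a.shape:
                raise ValueError(f"shape mismatch {p.data.shape} vs {a.shape}")
            p.data = np.asarray(a, dtype=np.float64).copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator):
        scale = np.sqrt(2.0 / (n_in + n_out))
        self.weight = Parameter(rng.normal(0.0, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out))

    def __call__(self, x: Tensor) -> Tensor:
        return matmul(x, self.weight) + self.bias


class LayerNorm(Module):
    def __init__(self, n: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(n))
        self.shift = Parameter(np.zeros(n))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = tmean(x, axis=-1, keepdims=True)
        xc = x - mu
        var = tmean(xc * xc, axis=-1, keepdims=True)
        return xc / sqrt(var + self.eps) * self.gain + self.shift


def leaky_relu(x: Tensor, alpha: float = 0.2) -> Tensor:
    return maximum_const(x, 0.0) + alpha * (x - maximum_const(x, 0.0))


class GRU(Module):
    """Single-layer gated recurrent unit over a step-count-agnostic sequence.

    Input: list of (batch, n_in) tensors, one per sequence step.  Returns the
    final hidden state (batch, n_hidden).
    """

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        self.n_hidden = n_hidden
        s_in = np.sqrt(1.0 / n_in)
        s_h = np.sqrt(1.0 / n_hidden)
        self.w_x = Parameter(rng.uniform(-s_in, s_in, size=(n_in, 3 * n_hidden)))
        self.w_h = Parameter(rng.uniform(-s_h, s_h, size=(n_hidden, 3 * n_hidden)))
        self.b = Parameter(np.zeros(3 * n_hidden))

    def __call__(self, steps, h0: Tensor | None = None) -> Tensor:
        if len(steps) == 0:
            raise ValueError("GRU requires at least one input step")
        n = self.n_hidden
        batch = steps[0].shape[0]
        h = h0 if h0 is not None else Tensor(np.zeros((batch, n)))
        for x in steps:
            gx = matmul(x, self.w_x) + self.b
            gh = matmul(h, self.w_h)
            r = sigmoid(gx[:, :n] + gh[:, :n])
            z = sigmoid(gx[:, n : 2 * n] + gh[:, n : 2 * n])
            c = tanh(gx[:, 2 * n :] + r * gh[:, 2 * n :])
            h = z * h + (1.0 - z) * c
        return h


class Adam:
    """Adam optimizer with bias correction."""

    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr, self.beta1, self.beta2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def step(self, grads):
        if len(grads) != len(self.params):
            raise ValueError("gradient count does not match parameter count")
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            gd = g.data if isinstance(g, Tensor) else np.asarray(g)
            m *= b1
            m += (1 - b1) * gd
            v *= b2
            v += (1 - b2) * gd * gd
            mhat = m / (1 - b1**self.t)
            vhat = v / (1 - b2**self.t)
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
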