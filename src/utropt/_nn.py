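"""Network building blocks on top of :mod:`utropt._autodiff`.

Layers hold their parameters as :class:`~utropt._autodiff.Tensor` leaves with
``requires_grad=True``; a module exposes them through ``parameters()`` as an
ordered ``dict`` of name → Tensor so weights can be averaged, checksummed and
serialized by key.
"""

from __future__ import annotations

import numpy as np

from ._autodiff import Tensor, concat, conv1d, softmax

ACTIVATIONS = ("relu", "elu", "tanh")


def apply_activation(x: Tensor, name: str) -> Tensor:
    if name == "relu":
        return x.relu()
    if name == "elu":
        return x.elu()
    if name == "tanh":
        return x.tanh()
    raise ValueError(f"unknown activation {name!r}; choose from {ACTIVATIONS}")


def _glorot(rng: np.random.Generator, shape, fan_in, fan_out) -> np.ndarray:
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape)


class Module:
    """Base: children registered as attributes; parameters discovered recursively."""

    def parameters(self) -> dict[str, Tensor]:
        params: dict[str, Tensor] = {}
        for name, value in vars(self).items():
            if isinstance(value, Tensor):
                params[name] = value
            elif isinstance(value, Module):
                for sub, t in value.parameters().items():
                    params[f"{name}.{sub}"] = t
            elif isinstance(value, (list, tuple)):
                for i, item in enumerate(value):
                    if isinstance(item, Module):
                        for sub, t in item.parameters().items():
                            params[f"{name}.{i}.{sub}"] = t
        return params

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.parameters().items()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        params = self.parameters()
        if set(params) != set(state):
            raise ValueError("state keys do not match module parameters")
        for k, v in params.items():
            if v.data.shape != state[k].shape:
                raise ValueError(f"shape mismatch for parameter {k!r}")
            v.data = np.asarray(state[k], dtype=np.float64).copy()

    def set_trainable(self, flag: bool) -> None:
        for _, t in self.parameters().items():
            t.requires_grad = flag


class Dense(Module):
    def __init__(self, rng: np.random.Generator, d_in: int, d_out: int):
        self.W = Tensor(_glorot(rng, (d_in, d_out), d_in, d_out), requires_grad=True)
        self.b = Tensor(np.zeros(d_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.W + self.b


class Conv1d(Module):
    def __init__(self, rng: np.random.Generator, c_in: int, c_out: int, kernel: int):
        fan_in = c_in * kernel
        self.W = Tensor(_glorot(rng, (kernel, c_in, c_out), fan_in, c_out), requires_grad=True)
        self.b = Tensor(np.zeros(c_out), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return conv1d(x, self.W, self.b)


class ResidualConvBlock(Module):
    """conv → activation, with an additive skip (1×1 projection if widths differ)."""

    def __init__(self, rng, c_in: int, c_out: int, kernel: int, activation: str):
        self.conv = Conv1d(rng, c_in, c_out, kernel)
        self.activation = activation
        self.proj = Conv1d(rng, c_in, c_out, 1) if c_in != c_out else None

    def __call__(self, x: Tensor) -> Tensor:
        h = apply_activation(self.conv(x), self.activation)
        skip = self.proj(x) if self.proj is not None else x
        return h + skip

    def parameters(self):
        params = {f"conv.{k}": v for k, v in self.conv.parameters().items()}
        if self.proj is not None:
            params.update({f"proj.{k}": v for k, v in self.proj.parameters().items()})
        return params


class ResidualDenseBlock(Module):
    def __init__(self, rng, d_in: int, d_out: int, activation: str):
        self.dense = Dense(rng, d_in, d_out)
        self.activation = activation
        self.proj = Dense(rng, d_in, d_out) if d_in != d_out else None

    def __call__(self, x: Tensor) -> Tensor:
        h = apply_activation(self.dense(x), self.activation)
        skip = self.proj(x) if self.proj is not None else x
        return h + skip

    def parameters(self):
        params = {f"dense.{k}": v for k, v in self.dense.parameters().items()}
        if self.proj is not None:
            params.update({f"proj.{k}": v for k, v in self.proj.parameters().items()})
        return params


class GRU(Module):
    """Single-layer gated recurrent unit; returns the final hidden state.

    One recurrence step per sequence position: the input projection for all
    positions is computed in a single matmul, only the hidden-to-hidden
    product stays inside the loop.
    """

    def __init__(self, rng, d_in: int, d_hidden: int):
        self.Wx = Tensor(_glorot(rng, (d_in, 3 * d_hidden), d_in, d_hidden), requires_grad=True)
        self.Wh = Tensor(_glorot(rng, (d_hidden, 3 * d_hidden), d_hidden, d_hidden),
                         requires_grad=True)
        self.bx = Tensor(np.zeros(3 * d_hidden), requires_grad=True)
        self.bh = Tensor(np.zeros(3 * d_hidden), requires_grad=True)
        self.d_hidden = d_hidden

    def __call__(self, x: Tensor) -> Tensor:
        B, L, _ = x.shape
        H = self.d_hidden
        xp = x.reshape(B * L, -1) @ self.Wx + self.bx
        xp = xp.reshape(B, L, 3 * H)
        h = Tensor(np.zeros((B, H)))
        for t in range(L):
            xt = xp[:, t]
            hp = h @ self.Wh + self.bh
            r = (xt[:, :H] + hp[:, :H]).sigmoid()
            z = (xt[:, H:2 * H] + hp[:, H:2 * H]).sigmoid()
            n = (xt[:, 2 * H:] + r * hp[:, 2 * H:]).tanh()
            h = (1.0 - z) * n + z * h
        return h


class Adam:
    """Adam optimizer over a fixed dict of parameters."""

    def __init__(self, params: dict[str, Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.v = {k: np.zeros_like(v.data) for k, v in params.items()}
        self.t = 0

    def zero_grad(self) -> None:
        for p in self.params.values():
            p.grad = None

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, p in self.params.items():
            if p.grad is None:
                continue
            self.m[k] = b1 * self.m[k] + (1 - b1) * p.grad
            self.v[k] = b2 * self.v[k] + (1 - b2) * p.grad ** 2
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


__all__ = [
    "ACTIVATIONS", "Adam", "Conv1d", "Dense", "GRU", "Module",
    "ResidualConvBlock", "ResidualDenseBlock", "apply_activation",
    "Tensor", "concat", "conv1d", "softmax",
]
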