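"""Small neural-network toolkit on top of :mod:`gridner._autodiff`.

Provides parameter containers, linear/embedding/layer-norm layers, a
one-hidden-layer GELU perceptron, the AdamW optimizer and a linear
warmup/decay learning-rate schedule — everything the grid model composes.
"""

from __future__ import annotations

import math
from typing import Iterable, Iterator

import numpy as np

from ._autodiff import Tensor, concat

__all__ = [
    "Parameter",
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "MLP",
    "AdamW",
    "linear_warmup_decay",
]


class Parameter(Tensor):
    def __init__(self, data, name: str = ""):
        super().__init__(data, requires_grad=True, name=name)
        self.requires_grad = True  # immune to no_grad at construction


class Module:
    """Lightweight parameter registry with recursive traversal."""

    def named_parameters(self, prefix: str = "") -> Iterator[tuple[str, Parameter]]:
        for key, val in vars(self).items():
            name = f"{prefix}{key}"
            if isinstance(val, Parameter):
                yield name, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=name + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{name}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{name}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: v.data.copy() for k, v in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


def normal_init(rng: np.random.Generator, shape, std: float = 0.02) -> np.ndarray:
    return rng.normal(0.0, std, size=shape)


def xavier_init(rng: np.random.Generator, fan_in: int, fan_out: int) -> np.ndarray:
    bound = math.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-bound, bound, size=(fan_in, fan_out))


class Linear(Module):
    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator, bias: bool = True):
        self.weight = Parameter(xavier_init(rng, d_in, d_out))
        self.bias = Parameter(np.zeros(d_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    def __init__(self, n: int, d: int, rng: np.random.Generator, std: float = 0.02):
        self.weight = Parameter(normal_init(rng, (n, d), std))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight.take_rows(idx)


class LayerNorm(Module):
    def __init__(self, d: int, eps: float = 1e-5):
        self.gain = Parameter(np.ones(d))
        self.bias = Parameter(np.zeros(d))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        centered = x - mu
        var = (centered**2).mean(axis=-1, keepdims=True)
        return self.gain * (centered / (var + self.eps) ** 0.5) + self.bias


class MLP(Module):
    """One hidden GELU layer; hidden width defaults to the output width."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 d_hidden: int | None = None):
        d_hidden = d_out if d_hidden is None else d_hidden
        self.fc1 = Linear(d_in, d_hidden, rng)
        self.fc2 = Linear(d_hidden, d_out, rng)

    def __call__(self, x: Tensor) -> Tensor:
        return self.fc2(self.fc1(x).gelu())


class AdamW:
    """Decoupled weight decay Adam.

    Parameter groups: pass ``[(params, lr_scale), ...]`` via ``groups`` or a
    flat parameter list. Weight decay is skipped for 1-D parameters (biases,
    norm gains), the usual transformer convention.
    """

    def __init__(self, params: Iterable[Parameter], lr: float = 1e-3,
                 betas=(0.9, 0.999), eps: float = 1e-8, weight_decay: float = 0.1):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.weight_decay = weight_decay
        self.t = 0
        self._m = [np.zeros_like(p.data) for p in self.params]
        self._v = [np.zeros_like(p.data) for p in self.params]

    def step(self, lr_scale: float = 1.0):
        self.t += 1
        lr = self.lr * lr_scale
        for p, m, v in zip(self.params, self._m, self._v):
            if p.grad is None:
                continue
            g = p.grad
            m *= self.b1
            m += (1 - self.b1) * g
            v *= self.b2
            v += (1 - self.b2) * g * g
            mhat = m / (1 - self.b1**self.t)
            vhat = v / (1 - self.b2**self.t)
            if p.data.ndim > 1 and self.weight_decay:
                p.data -= lr * self.weight_decay * p.data
            p.data -= lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self):
        for p in self.params:
            p.grad = None


def linear_warmup_decay(step: int, total_steps: int, warmup_frac: float = 0.1) -> float:
    """Linear warm-up to 1.0 then linear decay to 0; returns the LR scale."""
    warmup = max(1, int(round(warmup_frac * total_steps)))
    if step < warmup:
        return (step + 1) / warmup
    if total_steps <= warmup:
        return 1.0
    return max(0.0, (total_steps - step) / (total_steps - warmup))
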