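"""Minimal reverse-mode automatic differentiation over numpy arrays.

The stability model is small (~1.2M parameters at full size, far less in the
desk-scale presets), runs on CPU, and needs exact, replayable numerics for
invariance and gradient tests.  This module provides the few primitives the
graph-transformer needs: broadcast-aware elementwise ops, (batched) matmul,
reductions, indexing/concat/reshape, and a numerically safe softmax — plus
``Module``/``Parameter`` containers, AdamW and a weight EMA.

All arithmetic is float64.  Gradients are accumulated by topological sort of
the tape; ``Tensor.backward`` may only be called on scalars.
"""

from __future__ import annotations

import math
from typing import Callable, Iterable, Sequence

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "Linear",
    "Embedding",
    "LayerNorm",
    "AdamW",
    "EMA",
    "concat",
    "relu",
    "softmax",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum leading axes added by broadcasting
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: np.ndarray | None = None
        self.requires_grad = requires_grad
        self._backward: Callable[[], None] | None = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------
    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def item(self) -> float:
        return float(self.data)

    def detach(self) -> "Tensor":
        return Tensor(self.data)

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    @staticmethod
    def _wrap(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data: np.ndarray, parents: Sequence["Tensor"],
              backward: Callable[["Tensor"], None] | None) -> "Tensor":
        out = Tensor(data)
        out.requires_grad = any(p.requires_grad for p in parents)
        if out.requires_grad and backward is not None:
            out._parents = tuple(parents)
            out._backward = lambda: backward(out)
        return out

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = self._wrap(other)

        def bwd(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad, other.shape))

        return self._make(self.data + other.data, (self, other), bwd)

    __radd__ = __add__

    def __mul__(self, other):
        other = self._wrap(other)

        def bwd(out):
            if self.requires_grad:
                self._accum(_unbroadcast(out.grad * other.data, self.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(out.grad * self.data, other.shape))

        return self._make(self.data * other.data, (self, other), bwd)

    __rmul__ = __mul__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-self._wrap(other))

    def __rsub__(self, other):
        return self._wrap(other) + (-self)

    def __truediv__(self, other):
        other = self._wrap(other)
        return self * other ** (-1.0)

    def __pow__(self, p: float):
        def bwd(out):
            if self.requires_grad:
                self._accum(out.grad * p * self.data ** (p - 1.0))

        return self._make(self.data ** p, (self,), bwd)

    def __matmul__(self, other):
        other = self._wrap(other)

        def bwd(out):
            g = out.grad
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.shape))

        return self._make(self.data @ other.data, (self, other), bwd)

    # -- nonlinearities ---------------------------------------------------
    def exp(self):
        def bwd(out):
            if self.requires_grad:
                self._accum(out.grad * out.data)

        return self._make(np.exp(self.data), (self,), bwd)

    def log(self):
        def bwd(out):
            if self.requires_grad:
                self._accum(out.grad / self.data)

        return self._make(np.log(self.data), (self,), bwd)

    def relu(self):
        def bwd(out):
            if self.requires_grad:
                self._accum(out.grad * (self.data > 0))

        return self._make(np.maximum(self.data, 0.0), (self,), bwd)

    def abs(self):
        def bwd(out):
            if self.requires_grad:
                self._accum(out.grad * np.sign(self.data))

        return self._make(np.abs(self.data), (self,), bwd)

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False):
        def bwd(out):
            if not self.requires_grad:
                return
            g = out.grad
            if axis is not None and not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.shape).copy())

        return self._make(self.data.sum(axis=axis, keepdims=keepdims),
                          (self,), bwd)

    def mean(self, axis=None, keepdims: bool = False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape ops --------------------------------------------------------
    def reshape(self, *shape):
        old = self.shape

        def bwd(out):
            if self.requires_grad:
                self._accum(out.grad.reshape(old))

        return self._make(self.data.reshape(*shape), (self,), bwd)

    def transpose(self, *axes):
        inv = np.argsort(axes)

        def bwd(out):
            if self.requires_grad:
                self._accum(out.grad.transpose(*inv))

        return self._make(self.data.transpose(*axes), (self,), bwd)

    def __getitem__(self, idx):
        def bwd(out):
            if self.requires_grad:
                g = np.zeros_like(self.data)
                np.add.at(g, idx, out.grad)
                self._accum(g)

        return self._make(self.data[idx], (self,), bwd)

    # -- autodiff ---------------------------------------------------------
    def backward(self) -> None:
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS: environments can make deep graphs
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                if id(p) not in seen:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None:
                node._backward()


def concat(tensors: Sequence[Tensor], axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    data = np.concatenate([t.data for t in tensors], axis=axis)
    out = Tensor(data)
    out.requires_grad = any(t.requires_grad for t in tensors)
    if out.requires_grad:
        sizes = [t.data.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def bwd():
            for t, g in zip(tensors, np.split(out.grad, splits, axis=axis)):
                if t.requires_grad:
                    t._accum(g)

        out._parents = tuple(tensors)
        out._backward = bwd
    return out


def relu(x: Tensor) -> Tensor:
    return x.relu()


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    # shift by a detached max: softmax is shift-invariant, so the shift
    # carries no gradient and keeps exp() in range
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


class Parameter(Tensor):
    def __init__(self, data):
        super().__init__(data, requires_grad=True)


class Module:
    """Lightweight parameter container with train/eval mode."""

    def __init__(self):
        self.training = True

    def parameters(self) -> list[Parameter]:
        params: list[Parameter] = []
        for v in self.__dict__.values():
            if isinstance(v, Parameter):
                params.append(v)
            elif isinstance(v, Module):
                params.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        params.extend(item.parameters())
                    elif isinstance(item, Parameter):
                        params.append(item)
        return params

    def named_parameters(self, prefix: str = "") -> list[tuple[str, Parameter]]:
        out: list[tuple[str, Parameter]] = []
        for k, v in self.__dict__.items():
            name = f"{prefix}{k}"
            if isinstance(v, Parameter):
                out.append((name, v))
            elif isinstance(v, Module):
                out.extend(v.named_parameters(name + "."))
            elif isinstance(v, (list, tuple)):
                for i, item in enumerate(v):
                    if isinstance(item, Module):
                        out.extend(item.named_parameters(f"{name}.{i}."))
                    elif isinstance(item, Parameter):
                        out.append((f"{name}.{i}", item))
        return out

    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def zero_grad(self) -> None:
        for p in self.parameters():
            p.grad = None

    def train(self) -> "Module":
        self.training = True
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.train()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.train()
        return self

    def eval(self) -> "Module":
        self.training = False
        for v in self.__dict__.values():
            if isinstance(v, Module):
                v.eval()
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        item.eval()
        return self

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray]) -> None:
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"missing parameters in state dict: {sorted(missing)}")
        for k, p in own.items():
            arr = np.asarray(state[k], dtype=np.float64)
            if arr.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}: {arr.shape} vs {p.data.shape}")
            p.data = arr.copy()


class Linear(Module):
    def __init__(self, n_in: int, n_out: int, rng: np.random.Generator,
                 bias: bool = True):
        super().__init__()
        scale = 1.0 / math.sqrt(n_in)
        self.weight = Parameter(rng.uniform(-scale, scale, size=(n_in, n_out)))
        self.bias = Parameter(np.zeros(n_out)) if bias else None

    def __call__(self, x: Tensor) -> Tensor:
        y = x @ self.weight
        if self.bias is not None:
            y = y + self.bias
        return y


class Embedding(Module):
    def __init__(self, n_vocab: int, dim: int, rng: np.random.Generator):
        super().__init__()
        self.weight = Parameter(rng.normal(0.0, 1.0, size=(n_vocab, dim)))

    def __call__(self, idx: np.ndarray) -> Tensor:
        return self.weight[np.asarray(idx, dtype=np.intp)]


class LayerNorm(Module):
    def __init__(self, dim: int, eps: float = 1e-5):
        super().__init__()
        self.gamma = Parameter(np.ones(dim))
        self.beta = Parameter(np.zeros(dim))
        self.eps = eps

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc * (var + self.eps) ** (-0.5) * self.gamma + self.beta


class AdamW:
    """AdamW with per-group learning rates and decoupled weight decay."""

    def __init__(self, param_groups: Iterable[dict], betas=(0.9, 0.999),
                 eps: float = 1e-8):
        self.groups = [dict(g) for g in param_groups]
        for g in self.groups:
            g.setdefault("weight_decay", 0.0)
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self._m: dict[int, np.ndarray] = {}
        self._v: dict[int, np.ndarray] = {}

    def step(self) -> None:
        self.t += 1
        b1, b2 = self.b1, self.b2
        for g in self.groups:
            lr, wd = g["lr"], g["weight_decay"]
            for p in g["params"]:
                if p.grad is None:
                    continue
                key = id(p)
                m = self._m.setdefault(key, np.zeros_like(p.data))
                v = self._v.setdefault(key, np.zeros_like(p.data))
                m *= b1
                m += (1 - b1) * p.grad
                v *= b2
                v += (1 - b2) * p.grad ** 2
                mhat = m / (1 - b1 ** self.t)
                vhat = v / (1 - b2 ** self.t)
                p.data -= lr * (mhat / (np.sqrt(vhat) + self.eps) + wd * p.data)

    def zero_grad(self) -> None:
        for g in self.groups:
            for p in g["params"]:
                p.grad = None


class EMA:
    """Exponential moving average of model weights.

    shadow <- eta * shadow + (1 - eta) * live.  Evaluation uses the shadow
    weights; ``copy_to``/``restore`` swap them in and out of the model.
    """

    def __init__(self, module: Module, eta: float = 0.99):
        if not (0.0 <= eta < 1.0):
            raise ValueError("eta must be in [0, 1)")
        self.eta = eta
        self.shadow = {k: p.data.copy() for k, p in module.named_parameters()}
        self._backup: dict[str, np.ndarray] | None = None

    def update(self, module: Module) -> None:
        for k, p in module.named_parameters():
            s = self.shadow[k]
            if s.shape != p.data.shape:
                raise ValueError(f"shape mismatch for {k}")
            s *= self.eta
            s += (1.0 - self.eta) * p.data

    def copy_to(self, module: Module) -> None:
        self._backup = {k: p.data.copy() for k, p in module.named_parameters()}
        for k, p in module.named_parameters():
            p.data = self.shadow[k].copy()

    def restore(self, module: Module) -> None:
        if self._backup is None:
            raise RuntimeError("no backup to restore; call copy_to first")
        for k, p in module.named_parameters():
            p.data = self._backup[k]
        self._backup = None
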