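"""Minimal reverse-mode automatic differentiation over numpy arrays.

The network in this package is small (tens of thousands of parameters,
sequences of a few dozen days), so a compact tape-based autodiff core is
sufficient and keeps the whole model stack dependency-free and exactly
reproducible on CPU.  Every differentiable layer in :mod:`prcrs.network`
is composed from the primitives here; gradients are verified against
central finite differences in the test suite.

Only the operations the model needs are implemented: broadcasting
arithmetic, matmul (with batch dimensions), reductions, exp/log/sqrt/tanh,
relu, slicing, axis manipulation, padding and repetition.
"""

from __future__ import annotations

from typing import Callable, List, Optional, Sequence, Tuple, Union

import numpy as np

ArrayLike = Union[np.ndarray, float, int]


def _unbroadcast(grad: np.ndarray, shape: Tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    nd_extra = grad.ndim - len(shape)
    if nd_extra > 0:
        grad = grad.sum(axis=tuple(range(nd_extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """A numpy array plus the tape bookkeeping for reverse-mode gradients."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(
        self,
        data: ArrayLike,
        requires_grad: bool = False,
        parents: Sequence["Tensor"] = (),
        backward: Optional[Callable[[np.ndarray], None]] = None,
    ):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad: Optional[np.ndarray] = None
        self.requires_grad = requires_grad
        self._parents = tuple(parents)
        self._backward = backward

    # -- basics ------------------------------------------------------------
    @property
    def shape(self) -> Tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    def __repr__(self) -> str:
        return f"Tensor(shape={self.shape}, requires_grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data.copy())

    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self, grad: Optional[np.ndarray] = None) -> None:
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without grad requires a scalar")
            grad = np.ones_like(self.data)
        topo: List[Tensor] = []
        seen = set()

        def visit(t: Tensor) -> None:
            if id(t) in seen or not (t.requires_grad or t._parents):
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)

        visit(self)
        self._accum(np.asarray(grad, dtype=np.float64))
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)

    # -- arithmetic --------------------------------------------------------
    def __add__(self, other: "TensorLike") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other: "TensorLike") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self) -> "Tensor":
        return self * (-1.0)

    def __sub__(self, other: "TensorLike") -> "Tensor":
        return self + (-as_tensor(other))

    def __rsub__(self, other: "TensorLike") -> "Tensor":
        return as_tensor(other) + (-self)

    def __truediv__(self, other: "TensorLike") -> "Tensor":
        return self * as_tensor(other).pow(-1.0)

    def __rtruediv__(self, other: "TensorLike") -> "Tensor":
        return as_tensor(other) * self.pow(-1.0)

    def pow(self, p: float) -> "Tensor":
        out = Tensor(np.power(self.data, p), parents=(self,))

        def bw(g: np.ndarray) -> None:
            self._accum(g * p * np.power(self.data, p - 1.0))

        out._backward = bw
        return out

    def sqrt(self) -> "Tensor":
        return self.pow(0.5)

    def exp(self) -> "Tensor":
        out = Tensor(np.exp(self.data), parents=(self,))

        def bw(g: np.ndarray) -> None:
            self._accum(g * out.data)

        out._backward = bw
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), parents=(self,))

        def bw(g: np.ndarray) -> None:
            self._accum(g / self.data)

        out._backward = bw
        return out

    def tanh(self) -> "Tensor":
        out = Tensor(np.tanh(self.data), parents=(self,))

        def bw(g: np.ndarray) -> None:
            self._accum(g * (1.0 - out.data**2))

        out._backward = bw
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(self.data, 0.0), parents=(self,))

        def bw(g: np.ndarray) -> None:
            self._accum(g * (self.data > 0.0))

        out._backward = bw
        return out

    def silu(self) -> "Tensor":
        """x * sigmoid(x), the conformer convolution-module activation."""
        sig = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(self.data * sig, parents=(self,))

        def bw(g: np.ndarray) -> None:
            self._accum(g * (sig * (1.0 + self.data * (1.0 - sig))))

        out._backward = bw
        return out

    # -- linear algebra ----------------------------------------------------
    def matmul(self, other: "TensorLike") -> "Tensor":
        other = as_tensor(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def bw(g: np.ndarray) -> None:
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            self._accum(_unbroadcast(ga, a.shape))
            other._accum(_unbroadcast(gb, b.shape))

        out._backward = bw
        return out

    __matmul__ = matmul

    # -- reductions --------------------------------------------------------
    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), parents=(self,))

        def bw(g: np.ndarray) -> None:
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
                return
            if not keepdims:
                g = np.expand_dims(g, axis)
            self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._backward = bw
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # -- shape manipulation ------------------------------------------------
    def reshape(self, *shape: int) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))

        def bw(g: np.ndarray) -> None:
            self._accum(g.reshape(self.data.shape))

        out._backward = bw
        return out

    def swapaxes(self, a: int, b: int) -> "Tensor":
        out = Tensor(np.swapaxes(self.data, a, b), parents=(self,))

        def bw(g: np.ndarray) -> None:
            self._accum(np.swapaxes(g, a, b))

        out._backward = bw
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], parents=(self,))

        def bw(g: np.ndarray) -> None:
            full = np.zeros_like(self.data)
            np.add.at(full, idx, g)
            self._accum(full)

        out._backward = bw
        return out

    def pad_axis(self, axis: int, before: int, after: int) -> "Tensor":
        """Zero-pad along one axis."""
        pads = [(0, 0)] * self.data.ndim
        pads[axis] = (before, after)
        out = Tensor(np.pad(self.data, pads), parents=(self,))
        sl = [slice(None)] * self.data.ndim
        sl[axis] = slice(before, before + self.data.shape[axis])
        sl = tuple(sl)

        def bw(g: np.ndarray) -> None:
            self._accum(g[sl])

        out._backward = bw
        return out

    def repeat_axis(self, axis: int, reps: int) -> "Tensor":
        """Nearest-neighbour repetition along one axis (upsampling)."""
        out = Tensor(np.repeat(self.data, reps, axis=axis), parents=(self,))

        def bw(g: np.ndarray) -> None:
            shp = list(self.data.shape)
            shp.insert(axis + 1, reps)
            self._accum(g.reshape(shp).sum(axis=axis + 1))

        out._backward = bw
        return out


TensorLike = Union[Tensor, np.ndarray, float, int]


def as_tensor(x: TensorLike) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


# ---------------------------------------------------------------------------
# Composite functions


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)  # constant shift
    e = shifted.exp()
    return e / e.sum(axis=axis, keepdims=True)


def log_softmax(x: Tensor, axis: int = -1) -> Tensor:
    shifted = x - np.max(x.data, axis=axis, keepdims=True)
    return shifted - shifted.exp().sum(axis=axis, keepdims=True).log()


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Normalise the trailing (channel) axis to zero mean / unit variance."""
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + eps).pow(-0.5) * gamma + beta


def depthwise_conv1d(x: Tensor, weight: Tensor, bias: Optional[Tensor] = None,
                     causal: bool = False) -> Tensor:
    """Per-channel temporal convolution with zero padding, output length T.

    ``x``: (B, T, D); ``weight``: (K, D).  ``causal`` pads on the left only,
    so output day ``t`` depends on input days ``t-K+1 .. t``; otherwise
    'same' centred padding is used (K odd).
    """
    k = weight.shape[0]
    t = x.shape[1]
    if causal:
        xp = x.pad_axis(1, k - 1, 0)
    else:
        half = k // 2
        xp = x.pad_axis(1, half, half)
    out = None
    for i in range(k):
        term = xp[:, i : i + t, :] * weight[i]
        out = term if out is None else out + term
    if bias is not None:
        out = out + bias
    return out
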