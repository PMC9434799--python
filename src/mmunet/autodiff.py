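"""Minimal reverse-mode automatic differentiation over NumPy arrays.

The segmentation network needs only a small, fixed vocabulary of array
operations: stride-1 (possibly dilated) 2-D convolution, 2x2 stride-2
transposed convolution, 2x2 max pooling, batch normalization, elementwise
arithmetic with broadcasting, channel concatenation, reductions, matrix
multiplication and the usual pointwise nonlinearities.  Each operation
records a backward closure on a :class:`Tensor`; :meth:`Tensor.backward`
replays them in reverse topological order.

Convolutions are evaluated as tensordot contractions over strided sliding
windows, so the heavy lifting happens inside BLAS.  Gradients with respect
to convolution inputs are themselves expressed as convolutions of the
(zero-interleaved or padded) upstream gradient with the spatially flipped
kernel, which keeps the backward pass at the same cost as the forward one.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "as_tensor",
    "concat",
    "sigmoid",
    "relu",
    "conv2d",
    "conv_transpose2d_2x2",
    "max_pool2d_2x2",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum ``grad`` over the axes that were broadcast to reach its shape."""
    if grad.shape == shape:
        return grad
    ndim_diff = grad.ndim - len(shape)
    if ndim_diff > 0:
        grad = grad.sum(axis=tuple(range(ndim_diff)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """An array node in the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")
    __array_priority__ = 100  # keep numpy from hijacking reflected operators

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data)
        self.grad: np.ndarray | None = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._parents: tuple[Tensor, ...] = ()

    # -- plumbing ---------------------------------------------------------

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def ndim(self) -> int:
        return self.data.ndim

    @property
    def dtype(self):
        return self.data.dtype

    def __repr__(self) -> str:  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.requires_grad})"

    def detach(self) -> "Tensor":
        return Tensor(self.data, requires_grad=False)

    def _accumulate(self, grad: np.ndarray) -> None:
        if self.grad is None:
            self.grad = grad.astype(self.data.dtype, copy=True)
        else:
            self.grad += grad

    def backward(self, grad: np.ndarray | None = None) -> None:
        """Backpropagate from this (typically scalar) tensor."""
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without a gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:  # iterative DFS; graphs here are deep
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self._accumulate(np.asarray(grad, dtype=self.data.dtype))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)
                # interior activations are not reused; free eagerly
                if node._parents:
                    node.grad = None

    # -- elementwise arithmetic ------------------------------------------

    def __add__(self, other):
        other = as_tensor(other, self.dtype)
        out = Tensor(self.data + other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g, other.shape))

            out._backward = _bwd
        return out

    __radd__ = __add__

    def __neg__(self):
        return self * (-1.0)

    def __sub__(self, other):
        return self + (-as_tensor(other, self.dtype))

    def __rsub__(self, other):
        return as_tensor(other, self.dtype) + (-self)

    def __mul__(self, other):
        other = as_tensor(other, self.dtype)
        out = Tensor(self.data * other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g * other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(_unbroadcast(g * self.data, other.shape))

            out._backward = _bwd
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = as_tensor(other, self.dtype)
        out = Tensor(self.data / other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(_unbroadcast(g / other.data, self.shape))
                if other.requires_grad:
                    other._accumulate(
                        _unbroadcast(-g * self.data / (other.data**2), other.shape)
                    )

            out._backward = _bwd
        return out

    def __pow__(self, exponent: float):
        out = Tensor(self.data**exponent, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bwd(g):
                self._accumulate(g * exponent * self.data ** (exponent - 1))

            out._backward = _bwd
        return out

    def exp(self) -> "Tensor":
        e = np.exp(self.data)
        out = Tensor(e, self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * e)
        return out

    def log(self) -> "Tensor":
        out = Tensor(np.log(self.data), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g / self.data)
        return out

    def clamp(self, lo: float | None = None, hi: float | None = None) -> "Tensor":
        """Clip values; the gradient is passed through only where unclipped."""
        out = Tensor(np.clip(self.data, lo, hi), self.requires_grad)
        if out.requires_grad:
            mask = np.ones_like(self.data, dtype=bool)
            if lo is not None:
                mask &= self.data > lo
            if hi is not None:
                mask &= self.data < hi
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g * mask)
        return out

    # -- shape ops --------------------------------------------------------

    def reshape(self, *shape) -> "Tensor":
        orig = self.shape
        out = Tensor(self.data.reshape(*shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(g.reshape(orig))
        return out

    def __getitem__(self, idx) -> "Tensor":
        out = Tensor(self.data[idx], self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bwd(g):
                full = np.zeros_like(self.data)
                full[idx] = g
                self._accumulate(full)

            out._backward = _bwd
        return out

    def broadcast_to(self, shape: tuple[int, ...]) -> "Tensor":
        out = Tensor(np.broadcast_to(self.data, shape), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)
            out._backward = lambda g: self._accumulate(_unbroadcast(g, self.shape))
        return out

    # -- reductions -------------------------------------------------------

    def sum(self, axis=None, keepdims: bool = False) -> "Tensor":
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims), self.requires_grad)
        if out.requires_grad:
            out._parents = (self,)

            def _bwd(g):
                if axis is not None and not keepdims:
                    axes = axis if isinstance(axis, tuple) else (axis,)
                    g = np.expand_dims(g, axes)
                self._accumulate(np.broadcast_to(g, self.shape).copy())

            out._backward = _bwd
        return out

    def mean(self, axis=None, keepdims: bool = False) -> "Tensor":
        n = self.data.size if axis is None else np.prod(
            [self.shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims: bool = False) -> "Tensor":
        """Max reduction; ties send the full gradient to every argmax."""
        data = self.data.max(axis=axis, keepdims=True)
        out = Tensor(data if keepdims else np.squeeze(data, axis=axis), self.requires_grad)
        if out.requires_grad:
            mask = self.data == data
            out._parents = (self,)

            def _bwd(g):
                if not keepdims:
                    g = np.expand_dims(g, axis if isinstance(axis, tuple) else (axis,))
                self._accumulate(mask * g)

            out._backward = _bwd
        return out

    def min(self, axis, keepdims: bool = False) -> "Tensor":
        return -((-self).max(axis=axis, keepdims=keepdims))

    # -- linear algebra ---------------------------------------------------

    def matmul(self, other: "Tensor") -> "Tensor":
        out = Tensor(self.data @ other.data, self.requires_grad or other.requires_grad)
        if out.requires_grad:
            out._parents = (self, other)

            def _bwd(g):
                if self.requires_grad:
                    self._accumulate(g @ other.data.T)
                if other.requires_grad:
                    other._accumulate(self.data.T @ g)

            out._backward = _bwd
        return out


class Parameter(Tensor):
    """A learnable tensor: requires_grad is always on."""

    __slots__ = ("name",)

    def __init__(self, data, name: str = ""):
        super().__init__(np.asarray(data), requires_grad=True)
        self.name = name


def as_tensor(x, dtype=None) -> Tensor:
    if isinstance(x, Tensor):
        return x
    arr = np.asarray(x)
    if dtype is not None and arr.dtype != dtype:
        arr = arr.astype(dtype)
    return Tensor(arr)


# -- nonlinearities --------------------------------------------------------


def relu(x: Tensor) -> Tensor:
    out = Tensor(np.maximum(x.data, 0), x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g * (x.data > 0))
    return out


def sigmoid(x: Tensor) -> Tensor:
    from scipy.special import expit  # numerically stable for large |x|

    s = expit(x.data)
    out = Tensor(s, x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)
        out._backward = lambda g: x._accumulate(g * s * (1.0 - s))
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(
        np.concatenate([t.data for t in tensors], axis=axis),
        any(t.requires_grad for t in tensors),
    )
    if out.requires_grad:
        out._parents = tuple(tensors)
        sizes = [t.shape[axis] for t in tensors]
        splits = np.cumsum(sizes)[:-1]

        def _bwd(g):
            for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
                if t.requires_grad:
                    t._accumulate(piece)

        out._backward = _bwd
    return out


# -- convolution -----------------------------------------------------------


def _sliding_windows(x: np.ndarray, kh: int, kw: int, dil: int) -> np.ndarray:
    """View of shape (N, C, Hout, Wout, kh, kw) over an already padded x."""
    n, c, h, w = x.shape
    hout = h - (kh - 1) * dil
    wout = w - (kw - 1) * dil
    sn, sc, sh, sw = x.strides
    return np.lib.stride_tricks.as_strided(
        x,
        shape=(n, c, hout, wout, kh, kw),
        strides=(sn, sc, sh, sw, sh * dil, sw * dil),
        writeable=False,
    )


def _corr2d(x: np.ndarray, w: np.ndarray, pad: int, dil: int) -> np.ndarray:
    """Stride-1 cross-correlation: x (N,Cin,H,W), w (Cout,Cin,kh,kw)."""
    if pad:
        x = np.pad(x, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
    win = _sliding_windows(x, w.shape[2], w.shape[3], dil)
    # (N,Hout,Wout,Cout) <- contract over Cin, kh, kw
    y = np.tensordot(win, w, axes=([1, 4, 5], [1, 2, 3]))
    return np.ascontiguousarray(y.transpose(0, 3, 1, 2))


def conv2d(x: Tensor, w: Tensor, b: Tensor | None, pad: int, dilation: int = 1) -> Tensor:
    """2-D convolution (cross-correlation), stride 1, square dilation."""
    y = _corr2d(x.data, w.data, pad, dilation)
    if b is not None:
        y += b.data[None, :, None, None]
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(y, req)
    if req:
        parents = [x, w] + ([b] if b is not None else [])
        out._parents = tuple(parents)
        kh, kw = w.shape[2], w.shape[3]

        def _bwd(g):
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                xp = x.data
                if pad:
                    xp = np.pad(xp, ((0, 0), (0, 0), (pad, pad), (pad, pad)))
                win = _sliding_windows(xp, kh, kw, dilation)
                # (Cout,Cin,kh,kw) <- contract over N,Hout,Wout
                gw = np.tensordot(g, win, axes=([0, 2, 3], [0, 2, 3]))
                w._accumulate(gw)
            if x.requires_grad:
                # full correlation of g with the flipped kernel
                w_flip = w.data[:, :, ::-1, ::-1].swapaxes(0, 1)
                gx = _corr2d(g, w_flip, (kh - 1) * dilation - pad, dilation)
                x._accumulate(gx)

        out._backward = _bwd
    return out


def conv_transpose2d_2x2(x: Tensor, w: Tensor, b: Tensor | None) -> Tensor:
    """Transposed convolution with kernel 2x2 and stride 2 (exact upsampler).

    With kernel == stride, every output pixel receives exactly one kernel tap:
    y[n, o, 2i+a, 2j+c] = sum_k x[n, k, i, j] * w[k, o, a, c] + b[o].
    ``w`` has shape (Cin, Cout, 2, 2).
    """
    n, cin, h, wd = x.shape
    cout = w.shape[1]
    y = np.einsum("nkij,koac->noiajc", x.data, w.data, optimize=True)
    y = y.reshape(n, cout, 2 * h, 2 * wd)
    if b is not None:
        y += b.data[None, :, None, None]
    req = x.requires_grad or w.requires_grad or (b is not None and b.requires_grad)
    out = Tensor(np.ascontiguousarray(y), req)
    if req:
        parents = [x, w] + ([b] if b is not None else [])
        out._parents = tuple(parents)

        def _bwd(g):
            gr = g.reshape(n, cout, h, 2, wd, 2)
            if b is not None and b.requires_grad:
                b._accumulate(g.sum(axis=(0, 2, 3)))
            if w.requires_grad:
                gw = np.einsum("nkij,noiajc->koac", x.data, gr, optimize=True)
                w._accumulate(gw)
            if x.requires_grad:
                gx = np.einsum("noiajc,koac->nkij", gr, w.data, optimize=True)
                x._accumulate(gx)

        out._backward = _bwd
    return out


def max_pool2d_2x2(x: Tensor) -> Tensor:
    """2x2 max pooling with stride 2; ties route the gradient to the first max."""
    n, c, h, w = x.shape
    if h % 2 or w % 2:
        raise ValueError(f"max_pool2d_2x2 needs even spatial dims, got {h}x{w}")
    blocks = x.data.reshape(n, c, h // 2, 2, w // 2, 2).transpose(0, 1, 2, 4, 3, 5)
    flat = blocks.reshape(n, c, h // 2, w // 2, 4)
    idx = flat.argmax(axis=-1)
    out = Tensor(np.take_along_axis(flat, idx[..., None], axis=-1)[..., 0], x.requires_grad)
    if out.requires_grad:
        out._parents = (x,)

        def _bwd(g):
            gflat = np.zeros_like(flat)
            np.put_along_axis(gflat, idx[..., None], g[..., None], axis=-1)
            gx = (
                gflat.reshape(n, c, h // 2, w // 2, 2, 2)
                .transpose(0, 1, 2, 4, 3, 5)
                .reshape(n, c, h, w)
            )
            x._accumulate(gx)

        out._backward = _bwd
    return out
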