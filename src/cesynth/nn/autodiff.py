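"""Reverse-mode automatic differentiation on numpy float32 arrays.

A :class:`Tensor` wraps an ``ndarray`` and records, for every operation, a
closure that accumulates gradients into its inputs.  ``Tensor.backward()``
walks the recorded graph in reverse topological order.  The op set is the
minimum needed for convolutional encoder/decoder networks: broadcasting
arithmetic, matmul (2-D and batched 3-D), reductions, the usual pointwise
nonlinearities, shape ops, 2-D padding, convolution and transposed
convolution.  Everything is float32 and single threaded.
"""

from __future__ import annotations

import numpy as np

__all__ = ["Tensor", "cat", "conv2d", "conv_transpose2d", "pad2d", "softmax",
           "batch_norm_train"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``grad`` down to ``shape`` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    # sum over leading axes added by broadcasting
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    # sum over axes that were 1 in the original shape
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._backward = None
        self._prev = ()

    # ------------------------------------------------------------------ utils
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

    def numpy(self) -> np.ndarray:
        return self.data

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, requires_grad={self.requires_grad})"

    def _accum(self, g: np.ndarray):
        # First contribution borrows the array; a second one adds out of
        # place, so borrowed (possibly shared) buffers are never mutated.
        if self.grad is None:
            self.grad = g if g.dtype == np.float32 else g.astype(np.float32)
        else:
            self.grad = self.grad + g

    @staticmethod
    def _wrap(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))

    def _make(self, data, parents, backward) -> "Tensor":
        out = Tensor(data)
        if any(p.requires_grad for p in parents):
            out.requires_grad = True
            out._prev = tuple(parents)
            out._backward = backward
        return out

    # --------------------------------------------------------------- backward
    def backward(self, grad=None):
        if grad is None:
            if self.data.size != 1:
                raise ValueError("backward() without gradient requires a scalar")
            grad = np.ones_like(self.data)
        topo, visited = [], set()
        stack = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                topo.append(node)
                continue
            if id(node) in visited:
                continue
            visited.add(id(node))
            stack.append((node, True))
            for p in node._prev:
                if p.requires_grad and id(p) not in visited:
                    stack.append((p, False))
        self._accum(np.asarray(grad, dtype=np.float32))
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    # ------------------------------------------------------------- arithmetic
    def __add__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __mul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-Tensor._wrap(other))

    def __rsub__(self, other):
        return Tensor._wrap(other) + (-self)

    def __truediv__(self, other):
        other = Tensor._wrap(other)
        return self * other ** -1.0

    def __rtruediv__(self, other):
        return Tensor._wrap(other) * self ** -1.0

    def __pow__(self, p: float):
        p = float(p)
        out_data = self.data ** np.float32(p)

        def backward(g):
            if self.requires_grad:
                self._accum(g * p * self.data ** np.float32(p - 1.0))

        return self._make(out_data, (self,), backward)

    def __matmul__(self, other):
        other = Tensor._wrap(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    # -------------------------------------------------------------- reductions
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).astype(np.float32))
            else:
                gg = g
                if not keepdims:
                    gg = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(gg, self.data.shape).astype(np.float32))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        if axis is None:
            n = self.data.size
        else:
            axes = axis if isinstance(axis, tuple) else (axis,)
            n = int(np.prod([self.data.shape[a] for a in axes]))
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    # ------------------------------------------------------------- nonlinear
    def abs(self):
        out_data = np.abs(self.data)
        sign = np.sign(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * sign)

        return self._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)
        m = (self.data > 0).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                self._accum(g * m)

        return self._make(out_data, (self,), backward)

    def leaky_relu(self, slope: float = 0.2):
        m = np.where(self.data > 0, np.float32(1.0), np.float32(slope))
        out_data = self.data * m

        def backward(g):
            if self.requires_grad:
                self._accum(g * m)

        return self._make(out_data, (self,), backward)

    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data * out_data))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def exp(self):
        out_data = np.exp(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data)

        return self._make(out_data, (self,), backward)

    def log(self):
        out_data = np.log(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g / self.data)

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        return self ** 0.5

    def clip(self, lo: float, hi: float):
        """Clamp values; gradient passes only through unclipped entries."""
        out_data = np.clip(self.data, lo, hi)
        m = ((self.data >= lo) & (self.data <= hi)).astype(np.float32)

        def backward(g):
            if self.requires_grad:
                self._accum(g * m)

        return self._make(out_data, (self,), backward)

    # ------------------------------------------------------------- shape ops
    def reshape(self, *shape):
        if len(shape) == 1 and isinstance(shape[0], (tuple, list)):
            shape = tuple(shape[0])
        old = self.data.shape
        out_data = self.data.reshape(shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def transpose(self, *axes):
        if len(axes) == 1 and isinstance(axes[0], (tuple, list)):
            axes = tuple(axes[0])
        inv = np.argsort(axes)
        out_data = self.data.transpose(axes)

        def backward(g):
            if self.requires_grad:
                self._accum(g.transpose(inv))

        return self._make(out_data, (self,), backward)

    def __getitem__(self, idx):
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                gx = np.zeros_like(self.data)
                gx[idx] += g
                self._accum(gx)

        return self._make(out_data, (self,), backward)


# ---------------------------------------------------------------------- cat
def cat(tensors, axis: int = 0) -> Tensor:
    tensors = [Tensor._wrap(t) for t in tensors]
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def backward(g):
        for t, a, b in zip(tensors, offsets[:-1], offsets[1:]):
            if t.requires_grad:
                sl = [slice(None)] * g.ndim
                sl[axis] = slice(int(a), int(b))
                t._accum(g[tuple(sl)])

    out = Tensor(out_data)
    if any(t.requires_grad for t in tensors):
        out.requires_grad = True
        out._prev = tuple(tensors)
        out._backward = backward
    return out


def softmax(x: Tensor, axis: int = -1) -> Tensor:
    """Numerically stable softmax (the max shift is a detached constant)."""
    shift = Tensor(x.data.max(axis=axis, keepdims=True))
    e = (x - shift).exp()
    return e / e.sum(axis=axis, keepdims=True)


# --------------------------------------------------------------- batch norm
def batch_norm_train(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused training-mode batch normalization over (N, H, W) per channel.

    Returns (out, batch_mean, batch_var) with the statistics as plain arrays
    (for running-average updates).  gamma/beta are broadcast as (1,C,1,1).
    """
    axes = (0, 2, 3)
    n = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    invstd = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * invstd
    out_data = gamma.data * xhat + beta.data

    def backward(g):
        if gamma.requires_grad:
            gamma._accum((g * xhat).sum(axis=axes, keepdims=True))
        if beta.requires_grad:
            beta._accum(g.sum(axis=axes, keepdims=True))
        if x.requires_grad:
            dxhat = g * gamma.data
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accum(invstd * (dxhat - m1 - xhat * m2))

    out = x._make(out_data, (x, gamma, beta), backward)
    return out, mu.reshape(-1), (var * (n / max(n - 1, 1))).reshape(-1)


# ------------------------------------------------------------------ padding
def pad2d(x: Tensor, pad: int, mode: str = "zero") -> Tensor:
    """Pad the two trailing axes of an NCHW tensor.

    ``mode`` is ``"zero"`` or ``"reflect"``; reflect supports pad=1 only
    (all internal uses are 3x3 kernels).
    """
    if pad == 0:
        return x
    if mode == "zero":
        out_data = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad)))

        def backward(g):
            if x.requires_grad:
                x._accum(g[:, :, pad:-pad, pad:-pad])

        return x._make(out_data, (x,), backward)
    if mode == "reflect":
        if pad != 1:
            raise ValueError("reflect padding implemented for pad=1 only")
        out_data = np.pad(x.data, ((0, 0), (0, 0), (1, 1), (1, 1)), mode="reflect")

        def backward(g):
            if not x.requires_grad:
                return
            core = g[:, :, 1:-1, 1:-1].copy()
            # fold the reflected borders back onto their source rows/cols
            core[:, :, 1, :] += g[:, :, 0, 1:-1]
            core[:, :, -2, :] += g[:, :, -1, 1:-1]
            core[:, :, :, 1] += g[:, :, 1:-1, 0]
            core[:, :, :, -2] += g[:, :, 1:-1, -1]
            core[:, :, 1, 1] += g[:, :, 0, 0]
            core[:, :, 1, -2] += g[:, :, 0, -1]
            core[:, :, -2, 1] += g[:, :, -1, 0]
            core[:, :, -2, -2] += g[:, :, -1, -1]
            x._accum(core)

        return x._make(out_data, (x,), backward)
    raise ValueError(f"unknown pad mode {mode!r}")


# -------------------------------------------------------------- convolution
def _im2col_np(x: np.ndarray, kh: int, kw: int, stride: int, cols: np.ndarray):
    cols6 = cols.reshape(cols.shape[0], x.shape[1], kh, kw, -1)
    oh = (x.shape[2] - kh) // stride + 1
    ow = (x.shape[3] - kw) // stride + 1
    cols6 = cols6.reshape(cols.shape[0], x.shape[1], kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            cols6[:, :, i, j] = x[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride]


def _col2im_np(dcols: np.ndarray, dx: np.ndarray, kh: int, kw: int, stride: int):
    n, c, h, w = dx.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    dcols = dcols.reshape(n, c, kh, kw, oh, ow)
    for i in range(kh):
        for j in range(kw):
            dx[:, :, i : i + stride * oh : stride, j : j + stride * ow : stride] += dcols[:, :, i, j]


try:  # optional JIT acceleration of the patch gather/scatter
    import numba as _numba

    @_numba.njit(cache=False, fastmath=True)
    def _im2col_nb(x, kh, kw, stride, cols):  # pragma: no cover - jitted
        n, c, h, w = x.shape
        oh = (h - kh) // stride + 1
        ow = (w - kw) // stride + 1
        for ni in range(n):
            for ci in range(c):
                for i in range(kh):
                    for j in range(kw):
                        row = (ci * kh + i) * kw + j
                        for a in range(oh):
                            sa = a * stride + i
                            base = a * ow
                            for b in range(ow):
                                cols[ni, row, base + b] = x[ni, ci, sa, b * stride + j]

    @_numba.njit(cache=False, fastmath=True)
    def _col2im_nb(dcols, dx, kh, kw, stride):  # pragma: no cover - jitted
        n, c, h, w = dx.shape
        oh = (h - kh) // stride + 1
        ow = (w - kw) // stride + 1
        for ni in range(n):
            for ci in range(c):
                for i in range(kh):
                    for j in range(kw):
                        row = (ci * kh + i) * kw + j
                        for a in range(oh):
                            sa = a * stride + i
                            base = a * ow
                            for b in range(ow):
                                dx[ni, ci, sa, b * stride + j] += dcols[ni, row, base + b]

    _HAVE_NUMBA = True
except Exception:  # pragma: no cover - numba import failure
    _HAVE_NUMBA = False


def _im2col(x: np.ndarray, kh: int, kw: int, stride: int):
    """(N,C,H,W) -> (N, C*kh*kw, OH*OW) patch matrix (input already padded)."""
    n, c, h, w = x.shape
    oh = (h - kh) // stride + 1
    ow = (w - kw) // stride + 1
    cols = np.empty((n, c * kh * kw, oh * ow), dtype=np.float32)
    x = np.ascontiguousarray(x, dtype=np.float32)
    if _HAVE_NUMBA:
        _im2col_nb(x, kh, kw, stride, cols)
    else:
        _im2col_np(x, kh, kw, stride, cols)
    return cols, oh, ow


def _col2im(dcols: np.ndarray, xshape, kh: int, kw: int, stride: int):
    """Adjoint of :func:`_im2col`; returns gradient w.r.t. the padded input."""
    dx = np.zeros(xshape, dtype=np.float32)
    dcols = np.ascontiguousarray(dcols, dtype=np.float32)  # (N, C*kh*kw, OH*OW)
    if _HAVE_NUMBA:
        _col2im_nb(dcols, dx, kh, kw, stride)
    else:
        _col2im_np(dcols, dx, kh, kw, stride)
    return dx


def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None, stride: int = 1,
           pad: int = 0, pad_mode: str = "zero") -> Tensor:
    """2-D cross-correlation; weight layout (Cout, Cin, kh, kw)."""
    xp = pad2d(x, pad, pad_mode)
    co, ci, kh, kw = w.data.shape
    cols, oh, ow = _im2col(xp.data, kh, kw, stride)
    wm = w.data.reshape(co, ci * kh * kw)
    out_data = np.matmul(wm, cols).reshape(xp.data.shape[0], co, oh, ow)
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1, 1)
    parents = (xp, w) + ((b,) if b is not None else ())

    def backward(g):
        gf = g.reshape(g.shape[0], co, oh * ow)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dw = np.matmul(gf, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dw.reshape(co, ci, kh, kw))
        if xp.requires_grad:
            dcols = np.matmul(wm.T, gf)
            xp._accum(_col2im(dcols, xp.data.shape, kh, kw, stride))

    out = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out


def conv_transpose2d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride: int = 1) -> Tensor:
    """Transposed 2-D convolution (adjoint of strided conv, no padding).

    Weight layout (Cin, Cout, kh, kw); output side = (H-1)*stride + k.
    """
    ci, co, kh, kw = w.data.shape
    n, _, h, wd = x.data.shape
    oh = (h - 1) * stride + kh
    ow = (wd - 1) * stride + kw
    wm = w.data.reshape(ci, co * kh * kw)
    xf = x.data.reshape(n, ci, h * wd)
    cols = np.matmul(wm.T, xf)  # (N, Co*kh*kw, H*W)
    out_data = _col2im(cols, (n, co, oh, ow), kh, kw, stride)
    if b is not None:
        out_data = out_data + b.data.reshape(1, co, 1, 1)
    parents = (x, w) + ((b,) if b is not None else ())

    def backward(g):
        gcols, goh, gow = _im2col(g, kh, kw, stride)  # (N, Co*kh*kw, H*W)
        if b is not None and b.requires_grad:
            b._accum(g.sum(axis=(0, 2, 3)))
        if w.requires_grad:
            dwm = np.matmul(xf, gcols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(dwm.reshape(ci, co, kh, kw))
        if x.requires_grad:
            dxf = np.matmul(wm, gcols)
            x._accum(dxf.reshape(n, ci, h, wd))

    out = Tensor(out_data)
    if any(p.requires_grad for p in parents):
        out.requires_grad = True
        out._prev = parents
        out._backward = backward
    return out
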