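"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Provides exactly the operations the segmentation networks need: dense and
dilated 3x3/1x1 convolutions (stride 1, 'same' padding), non-overlapping
2x2 transposed convolution and 2x2 max pooling, batch normalization,
elementwise nonlinearities, row gathering and softmax for graph attention,
and an Adam optimizer.  Layout is NHWC throughout; all math is float32.

Gradients are checked against central finite differences in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

# ---------------------------------------------------------------------------
# Tensor and graph plumbing
# ---------------------------------------------------------------------------


class Tensor:
    """A NumPy array plus the closure needed to backpropagate through it."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad: bool = False):
        self.data = np.asarray(data, dtype=np.float32)
        self.requires_grad = bool(requires_grad)
        self.grad = None
        self._backward = None
        self._parents = ()

    @property
    def shape(self):
        return self.data.shape

    @property
    def ndim(self):
        return self.data.ndim

    def zero_grad(self):
        self.grad = None

    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        # topological order by iterative DFS
        topo, seen, stack = [], set(), [(self, False)]
        while stack:
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
        grads = {id(self): np.asarray(grad, dtype=np.float32)}
        for node in reversed(topo):
            g = grads.pop(id(node), None)
            if g is None:
                continue
            if node.requires_grad:
                node.grad = g if node.grad is None else node.grad + g
            if node._backward is None:
                continue
            for parent, pg in zip(node._parents, node._backward(g)):
                if pg is None or not _needs(parent):
                    continue
                key = id(parent)
                if key in grads:
                    grads[key] = grads[key] + pg
                else:
                    grads[key] = pg


def _needs(t: Tensor) -> bool:
    return t.requires_grad or t._backward is not None


def _result(data, parents, backward):
    out = Tensor(data)
    if any(_needs(p) for p in parents):
        out._parents = tuple(parents)
        out._backward = backward
    return out


def as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(grad, shape):
    """Sum grad down to `shape` (inverse of NumPy broadcasting)."""
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


# ---------------------------------------------------------------------------
# Elementwise and shape ops
# ---------------------------------------------------------------------------


def add(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _result(
        a.data + b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(g, b.shape)),
    )


def sub(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _result(
        a.data - b.data,
        (a, b),
        lambda g: (_unbroadcast(g, a.shape), _unbroadcast(-g, b.shape)),
    )


def mul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _result(
        a.data * b.data,
        (a, b),
        lambda g: (_unbroadcast(g * b.data, a.shape), _unbroadcast(g * a.data, b.shape)),
    )


def div(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _result(
        a.data / b.data,
        (a, b),
        lambda g: (
            _unbroadcast(g / b.data, a.shape),
            _unbroadcast(-g * a.data / (b.data * b.data), b.shape),
        ),
    )


def matmul(a, b):
    a, b = as_tensor(a), as_tensor(b)
    return _result(
        a.data @ b.data,
        (a, b),
        lambda g: (g @ b.data.T, a.data.T @ g),
    )


def relu(x):
    x = as_tensor(x)
    mask = x.data > 0
    return _result(x.data * mask, (x,), lambda g: (g * mask,))


def leaky_relu(x, slope: float = 0.2):
    x = as_tensor(x)
    mask = x.data > 0
    scale = np.where(mask, np.float32(1.0), np.float32(slope))
    return _result(x.data * scale, (x,), lambda g: (g * scale,))


def elu(x):
    x = as_tensor(x)
    pos = x.data > 0
    y = np.where(pos, x.data, np.expm1(np.minimum(x.data, 0.0)))
    return _result(
        y.astype(np.float32), (x,), lambda g: (g * np.where(pos, 1.0, y + 1.0).astype(np.float32),)
    )


def sigmoid(x):
    x = as_tensor(x)
    s = 1.0 / (1.0 + np.exp(-x.data))
    s = s.astype(np.float32)
    return _result(s, (x,), lambda g: (g * s * (1.0 - s),))


def reshape(x, shape):
    x = as_tensor(x)
    old = x.shape
    return _result(x.data.reshape(shape), (x,), lambda g: (g.reshape(old),))


def concat(tensors, axis: int = -1):
    tensors = [as_tensor(t) for t in tensors]
    sizes = [t.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        return tuple(np.split(g, splits, axis=axis))

    return _result(np.concatenate([t.data for t in tensors], axis=axis), tensors, backward)


def tsum(x, axis=None, keepdims: bool = False):
    x = as_tensor(x)
    shape = x.shape

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return (np.broadcast_to(g, shape).copy(),)

    return _result(x.data.sum(axis=axis, keepdims=keepdims), (x,), backward)


def tmean(x, axis=None, keepdims: bool = False):
    x = as_tensor(x)
    shape = x.shape
    n = x.data.size if axis is None else np.prod(
        [shape[a] for a in (axis if isinstance(axis, tuple) else (axis,))]
    )

    def backward(g):
        if axis is not None and not keepdims:
            g = np.expand_dims(g, axis)
        return ((np.broadcast_to(g, shape) / np.float32(n)).copy(),)

    return _result(x.data.mean(axis=axis, keepdims=keepdims), (x,), backward)


def gather_rows(x, idx):
    """y[i, m, :] = x[idx[i, m], :] for a 2-D features matrix x."""
    x = as_tensor(x)
    idx = np.asarray(idx)
    shape = x.shape

    def backward(g):
        dx = np.zeros(shape, dtype=np.float32)
        np.add.at(dx, idx, g)
        return (dx,)

    return _result(x.data[idx], (x,), backward)


def softmax(x, axis: int = -1):
    x = as_tensor(x)
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = (e / e.sum(axis=axis, keepdims=True)).astype(np.float32)

    def backward(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        return (s * (g - dot),)

    return _result(s, (x,), backward)


# ---------------------------------------------------------------------------
# Convolutions, pooling, batch norm
# ---------------------------------------------------------------------------


def _corr_same(x, w, dilation: int):
    """Stride-1 'same' correlation.  x: (N,H,W,Cin); w: (k,k,Cin,Cout).

    Returns (y, cols) where cols is the (N*H*W, k*k*Cin) im2col matrix,
    needed for the weight gradient.
    """
    k = w.shape[0]
    if k == 1:
        n, h, ww, c = x.shape
        cols = x.reshape(-1, c)
        y = cols @ w.reshape(c, -1)
        return y.reshape(n, h, ww, -1), cols
    pad = dilation * (k - 1) // 2
    xp = np.pad(x, ((0, 0), (pad, pad), (pad, pad), (0, 0)))
    kk = dilation * (k - 1) + 1
    win = sliding_window_view(xp, (kk, kk), axis=(1, 2))
    if dilation > 1:
        win = win[..., ::dilation, ::dilation]
    n, h, ww = win.shape[:3]
    cols = np.ascontiguousarray(win.transpose(0, 1, 2, 4, 5, 3)).reshape(n * h * ww, -1)
    y = cols @ w.reshape(-1, w.shape[-1])
    return y.reshape(n, h, ww, -1), cols


def conv2d(x, w, b=None, dilation: int = 1):
    """Stride-1 'same' 2-D convolution (cross-correlation), odd kernel."""
    x, w = as_tensor(x), as_tensor(w)
    if w.shape[0] % 2 == 0:
        raise ValueError("conv2d requires an odd kernel size")
    y, cols = _corr_same(x.data, w.data, dilation)
    if b is not None:
        b = as_tensor(b)
        y = y + b.data
        parents = (x, w, b)
    else:
        parents = (x, w)
    k, _, cin, cout = w.shape

    def backward(g):
        g2 = g.reshape(-1, cout)
        dw = (cols.T @ g2).reshape(w.shape)
        w_rot = w.data[::-1, ::-1].transpose(0, 1, 3, 2)  # (k,k,Cout,Cin)
        dx, _ = _corr_same(g, np.ascontiguousarray(w_rot), dilation)
        if b is not None:
            return dx, dw, g2.sum(axis=0)
        return dx, dw

    return _result(y, parents, backward)


def conv_transpose_2x2(x, w, b=None):
    """2x2 stride-2 transposed convolution (non-overlapping upsampling).

    x: (N,H,W,Cin); w: (2,2,Cin,Cout); output (N,2H,2W,Cout).
    """
    x, w = as_tensor(x), as_tensor(w)
    n, h, ww, cin = x.shape
    cout = w.shape[-1]
    y6 = np.tensordot(x.data, w.data, axes=([3], [2]))  # (N,H,W,2,2,Cout)
    y = y6.transpose(0, 1, 3, 2, 4, 5).reshape(n, 2 * h, 2 * ww, cout)
    if b is not None:
        b = as_tensor(b)
        y = y + b.data
        parents = (x, w, b)
    else:
        parents = (x, w)

    def backward(g):
        g6 = g.reshape(n, h, 2, ww, 2, cout).transpose(0, 1, 3, 2, 4, 5)
        dx = np.tensordot(g6, w.data, axes=([3, 4, 5], [0, 1, 3]))
        dw = np.tensordot(x.data, g6, axes=([0, 1, 2], [0, 1, 2]))  # (Cin,2,2,Cout)
        dw = dw.transpose(1, 2, 0, 3)
        if b is not None:
            return dx, dw, g.reshape(-1, cout).sum(axis=0)
        return dx, dw

    return _result(np.ascontiguousarray(y), parents, backward)


def maxpool_2x2(x):
    x = as_tensor(x)
    n, h, w, c = x.shape
    if h % 2 or w % 2:
        raise ValueError("maxpool_2x2 requires even spatial dimensions")
    win = x.data.reshape(n, h // 2, 2, w // 2, 2, c).transpose(0, 1, 3, 5, 2, 4)
    win = win.reshape(n, h // 2, w // 2, c, 4)
    idx = win.argmax(axis=-1)
    y = np.take_along_axis(win, idx[..., None], axis=-1)[..., 0]

    def backward(g):
        dwin = np.zeros_like(win)
        np.put_along_axis(dwin, idx[..., None], g[..., None], axis=-1)
        dx = dwin.reshape(n, h // 2, w // 2, c, 2, 2).transpose(0, 1, 4, 2, 5, 3)
        return (np.ascontiguousarray(dx.reshape(n, h, w, c)),)

    return _result(np.ascontiguousarray(y), (x,), backward)


def batchnorm(x, gamma, beta, state: dict, training: bool, momentum: float = 0.9, eps: float = 1e-5):
    """Batch normalization over all axes but the last (channel) axis.

    `state` holds running "mean"/"var" NumPy arrays, updated in training mode.
    """
    x, gamma, beta = as_tensor(x), as_tensor(gamma), as_tensor(beta)
    axes = tuple(range(x.ndim - 1))
    if training:
        mu = x.data.mean(axis=axes)
        var = x.data.var(axis=axes)
        state["mean"] = momentum * state["mean"] + (1.0 - momentum) * mu
        state["var"] = momentum * state["var"] + (1.0 - momentum) * var
    else:
        mu, var = state["mean"], state["var"]
    inv_std = (1.0 / np.sqrt(var + eps)).astype(np.float32)
    xhat = ((x.data - mu) * inv_std).astype(np.float32)
    y = gamma.data * xhat + beta.data
    m = np.prod([x.shape[a] for a in axes]) if axes else 1

    def backward(g):
        dgamma = (g * xhat).sum(axis=axes)
        dbeta = g.sum(axis=axes)
        dxhat = g * gamma.data
        if training:
            dx = (
                inv_std
                / m
                * (m * dxhat - dxhat.sum(axis=axes) - xhat * (dxhat * xhat).sum(axis=axes))
            )
        else:
            dx = dxhat * inv_std
        return dx.astype(np.float32), dgamma, dbeta

    return _result(y, (x, gamma, beta), backward)


def global_avg_pool(x):
    """(N,H,W,C) -> (N,C)."""
    return tmean(x, axis=(1, 2))


# ---------------------------------------------------------------------------
# Parameter initialization
# ---------------------------------------------------------------------------


def he_truncated_normal(rng: np.random.Generator, shape, fan_in: int):
    """He-scaled normal truncated at two standard deviations."""
    std = np.sqrt(2.0 / fan_in)
    draw = rng.standard_normal(size=shape)
    while True:
        bad = np.abs(draw) > 2.0
        if not bad.any():
            break
        draw[bad] = rng.standard_normal(size=int(bad.sum()))
    return (std * draw).astype(np.float32)


def glorot_uniform(rng: np.random.Generator, shape, fan_in: int, fan_out: int):
    limit = np.sqrt(6.0 / (fan_in + fan_out))
    return rng.uniform(-limit, limit, size=shape).astype(np.float32)


# ---------------------------------------------------------------------------
# Layers and modules
# ---------------------------------------------------------------------------


class Module:
    """Base class: children are discovered by attribute walk, params collected."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, Tensor) and val.requires_grad:
                yield path, val
            elif isinstance(val, Module):
                yield from val.named_parameters(path + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(f"{path}.{i}.")
                    elif isinstance(item, Tensor) and item.requires_grad:
                        yield f"{path}.{i}", item

    def parameters(self):
        return [p for _, p in self.named_parameters()]

    def named_buffers(self, prefix: str = ""):
        for name, val in vars(self).items():
            path = f"{prefix}{name}"
            if isinstance(val, dict) and "mean" in val and "var" in val:
                yield path + ".mean", val, "mean"
                yield path + ".var", val, "var"
            elif isinstance(val, Module):
                yield from val.named_buffers(path + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_buffers(f"{path}.{i}.")

    def state_dict(self):
        out = {name: p.data.copy() for name, p in self.named_parameters()}
        for name, holder, key in self.named_buffers():
            out[name] = np.asarray(holder[key]).copy()
        return out

    def load_state_dict(self, state: dict):
        for name, p in self.named_parameters():
            p.data = np.asarray(state[name], dtype=np.float32).copy()
        for name, holder, key in self.named_buffers():
            holder[key] = np.asarray(state[name], dtype=np.float32).copy()


class Conv2D(Module):
    def __init__(self, cin, cout, k=3, dilation=1, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        fan_in = k * k * cin
        self.w = Tensor(he_truncated_normal(rng, (k, k, cin, cout), fan_in), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None
        self.dilation = dilation

    def __call__(self, x, training=False):
        return conv2d(x, self.w, self.b, dilation=self.dilation)


class ConvTranspose2x2(Module):
    def __init__(self, cin, cout, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(he_truncated_normal(rng, (2, 2, cin, cout), 4 * cin), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True) if bias else None

    def __call__(self, x, training=False):
        return conv_transpose_2x2(x, self.w, self.b)


class BatchNorm(Module):
    def __init__(self, c, momentum=0.9, eps=1e-5):
        self.gamma = Tensor(np.ones(c, dtype=np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(c, dtype=np.float32), requires_grad=True)
        self.running = {"mean": np.zeros(c, dtype=np.float32), "var": np.ones(c, dtype=np.float32)}
        self.momentum = momentum
        self.eps = eps

    def __call__(self, x, training=False):
        return batchnorm(x, self.gamma, self.beta, self.running, training, self.momentum, self.eps)


class Dense(Module):
    def __init__(self, cin, cout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.w = Tensor(glorot_uniform(rng, (cin, cout), cin, cout), requires_grad=True)
        self.b = Tensor(np.zeros(cout, dtype=np.float32), requires_grad=True)

    def __call__(self, x, training=False):
        return add(matmul(x, self.w), self.b)


class ConvBNReLU(Module):
    def __init__(self, cin, cout, k=3, dilation=1, rng=None):
        self.conv = Conv2D(cin, cout, k, dilation, rng)
        self.bn = BatchNorm(cout)

    def __call__(self, x, training=False):
        return relu(self.bn(self.conv(x), training))


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------


class Adam:
    def __init__(self, params, lr=1e-4, beta1=0.9, beta2=0.999, eps=1e-8):
        self.params = list(params)
        self.lr = float(lr)
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.beta1**self.t
        b2t = 1.0 - self.beta2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.beta1 * self.m[i] + (1.0 - self.beta1) * g
            self.v[i] = self.beta2 * self.v[i] + (1.0 - self.beta2) * g * g
            mhat = self.m[i] / b1t
            vhat = self.v[i] / b2t
            p.data = p.data - self.lr * mhat / (np.sqrt(vhat) + self.eps)
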