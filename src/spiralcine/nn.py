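"""Minimal reverse-mode automatic differentiation on numpy arrays.

Implements exactly the operator set the disentangled reconstruction/
segmentation model needs — 2-D convolution (im2col), nearest-neighbor
upsampling, batch normalization, FiLM-style modulation, channel softmax,
straight-through binarization — together with module/parameter management
and an Adam optimizer.  Arrays are float32 throughout; gradients are
accumulated on a dynamically built tape and released after each backward
pass.
"""

from __future__ import annotations

import numpy as np


class Tensor:
    """A numpy array with a gradient and a backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_prev")

    def __init__(self, data, requires_grad: bool = False, _prev=()):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = requires_grad
        self._backward = None
        self._prev = _prev

    @property
    def shape(self):
        return self.data.shape

    # ------------------------------------------------------------------
    def backward(self, grad=None):
        if grad is None:
            grad = np.ones_like(self.data)
        topo, seen = [], set()

        def visit(t):
            if id(t) in seen:
                return
            seen.add(id(t))
            for p in t._prev:
                visit(p)
            topo.append(t)

        visit(self)
        self.grad = np.asarray(grad, dtype=np.float32)
        for t in reversed(topo):
            if t._backward is not None and t.grad is not None:
                t._backward(t.grad)
        # free the tape
        for t in topo:
            t._backward = None
            t._prev = ()

    def _accum(self, g):
        if not self.requires_grad and self._backward is None and not self._prev:
            return
        g = g.astype(np.float32, copy=False)
        self.grad = g if self.grad is None else self.grad + g

    # convenience operators ------------------------------------------------
    def __add__(self, other):
        return add(self, _wrap(other))

    __radd__ = __add__

    def __mul__(self, other):
        return mul(self, _wrap(other))

    __rmul__ = __mul__

    def __sub__(self, other):
        return add(self, mul(_wrap(other), _const(-1.0)))

    def __rsub__(self, other):
        return add(_wrap(other), mul(self, _const(-1.0)))

    def __neg__(self):
        return mul(self, _const(-1.0))

    def __truediv__(self, other):
        if isinstance(other, (int, float)):
            return mul(self, _const(1.0 / other))
        return mul(self, power(other, -1.0))

    def sum(self, axis=None, keepdims=False):
        return tsum(self, axis, keepdims)

    def mean(self, axis=None, keepdims=False):
        return tmean(self, axis, keepdims)

    def reshape(self, *shape):
        return reshape(self, shape)


def _wrap(x):
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


def _const(v):
    return Tensor(np.float32(v))


def _unbroadcast(grad, shape):
    """Sum gradient over broadcast dimensions back to ``shape``."""
    g = grad
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for i, s in enumerate(shape):
        if s == 1 and g.shape[i] != 1:
            g = g.sum(axis=i, keepdims=True)
    return g.reshape(shape)


def _node(data, parents, backward):
    out = Tensor(data, _prev=tuple(p for p in parents if isinstance(p, Tensor)))
    out._backward = backward
    return out


# -- elementwise ----------------------------------------------------------

def add(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data + b.data

    def backward(g):
        a._accum(_unbroadcast(g, a.data.shape))
        b._accum(_unbroadcast(g, b.data.shape))

    return _node(out_data, (a, b), backward)


def mul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data * b.data

    def backward(g):
        a._accum(_unbroadcast(g * b.data, a.data.shape))
        b._accum(_unbroadcast(g * a.data, b.data.shape))

    return _node(out_data, (a, b), backward)


def power(a: Tensor, p: float) -> Tensor:
    out_data = a.data ** p

    def backward(g):
        a._accum(g * p * a.data ** (p - 1))

    return _node(out_data, (a,), backward)


def exp(a: Tensor) -> Tensor:
    out_data = np.exp(a.data)

    def backward(g):
        a._accum(g * out_data)

    return _node(out_data, (a,), backward)


def log(a: Tensor, eps: float = 1e-8) -> Tensor:
    out_data = np.log(a.data + eps)

    def backward(g):
        a._accum(g / (a.data + eps))

    return _node(out_data, (a,), backward)


def tabs(a: Tensor) -> Tensor:
    out_data = np.abs(a.data)

    def backward(g):
        a._accum(g * np.sign(a.data))

    return _node(out_data, (a,), backward)


def leaky_relu(a: Tensor, slope: float = 0.1) -> Tensor:
    pos = a.data > 0
    out_data = np.where(pos, a.data, np.float32(slope) * a.data)

    def backward(g):
        a._accum(np.where(pos, g, np.float32(slope) * g))

    return _node(out_data, (a,), backward)


def batch_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5):
    """Fused batch normalization over (N, H, W) per channel (training mode).

    Returns (output, batch_mean, batch_var) with the standard closed-form
    backward pass; cheaper than composing it from primitive ops.
    """
    axes = (0, 2, 3)
    ne = x.data.shape[0] * x.data.shape[2] * x.data.shape[3]
    mu = x.data.mean(axis=axes, keepdims=True)
    xc = x.data - mu
    var = (xc * xc).mean(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = xc * inv
    c = x.data.shape[1]
    out_data = gamma.data.reshape(1, c, 1, 1) * xhat + beta.data.reshape(1, c, 1, 1)

    def backward(g):
        gamma._accum((g * xhat).sum(axis=axes))
        beta._accum(g.sum(axis=axes))
        dxhat = g * gamma.data.reshape(1, c, 1, 1)
        s1 = dxhat.sum(axis=axes, keepdims=True)
        s2 = (dxhat * xhat).sum(axis=axes, keepdims=True)
        x._accum((inv / ne) * (ne * dxhat - s1 - xhat * s2))

    out = _node(out_data, (x, gamma, beta), backward)
    return out, mu.reshape(c), var.reshape(c)


def sigmoid(a: Tensor) -> Tensor:
    out_data = 1.0 / (1.0 + np.exp(-a.data))

    def backward(g):
        a._accum(g * out_data * (1 - out_data))

    return _node(out_data, (a,), backward)


def binarize_ste(a: Tensor, threshold: float = 0.5) -> Tensor:
    """Hard threshold with a straight-through (identity) gradient."""
    out_data = (a.data > threshold).astype(np.float32)

    def backward(g):
        a._accum(g)

    return _node(out_data, (a,), backward)


def softmax(a: Tensor, axis: int = 1) -> Tensor:
    x = a.data - a.data.max(axis=axis, keepdims=True)
    e = np.exp(x)
    out_data = e / e.sum(axis=axis, keepdims=True)

    def backward(g):
        dot = (g * out_data).sum(axis=axis, keepdims=True)
        a._accum(out_data * (g - dot))

    return _node(out_data, (a,), backward)


# -- shape ops ------------------------------------------------------------

def reshape(a: Tensor, shape) -> Tensor:
    old = a.data.shape
    out_data = a.data.reshape(shape)

    def backward(g):
        a._accum(g.reshape(old))

    return _node(out_data, (a,), backward)


def concat(tensors, axis: int = 1) -> Tensor:
    out_data = np.concatenate([t.data for t in tensors], axis=axis)
    sizes = [t.data.shape[axis] for t in tensors]
    splits = np.cumsum(sizes)[:-1]

    def backward(g):
        for t, piece in zip(tensors, np.split(g, splits, axis=axis)):
            t._accum(piece)

    return _node(out_data, tuple(tensors), backward)


def tsum(a: Tensor, axis=None, keepdims=False) -> Tensor:
    out_data = a.data.sum(axis=axis, keepdims=keepdims)

    def backward(g):
        g2 = g
        if axis is not None and not keepdims:
            g2 = np.expand_dims(g2, axis)
        a._accum(np.broadcast_to(g2, a.data.shape).copy())

    return _node(out_data, (a,), backward)


def tmean(a: Tensor, axis=None, keepdims=False) -> Tensor:
    n = a.data.size if axis is None else np.prod(
        [a.data.shape[i] for i in np.atleast_1d(axis)])
    return mul(tsum(a, axis, keepdims), _const(1.0 / n))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    out_data = a.data @ b.data

    def backward(g):
        a._accum(g @ b.data.swapaxes(-1, -2))
        b._accum(a.data.swapaxes(-1, -2) @ g)

    return _node(out_data, (a, b), backward)


def upsample_nearest(a: Tensor, scale: int = 2) -> Tensor:
    out_data = a.data.repeat(scale, axis=2).repeat(scale, axis=3)

    def backward(g):
        n, c, h, w = a.data.shape
        a._accum(g.reshape(n, c, h, scale, w, scale).sum(axis=(3, 5)))

    return _node(out_data, (a,), backward)


# -- convolution ----------------------------------------------------------

def conv2d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride: int = 1, pad: int = 0) -> Tensor:
    """2-D convolution, NCHW layout, zero padding.

    Evaluated by im2col: the padded input is expanded into a column matrix
    once and both the forward pass and the weight/input gradients become
    single large GEMMs.
    """
    f, cin, kh, kw = w.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (pad, pad), (pad, pad))) if pad else x.data
    n, _, hp, wp = xp.shape
    ho = (hp - kh) // stride + 1
    wo = (wp - kw) // stride + 1
    s0, s1, s2, s3 = xp.strides
    windows = np.lib.stride_tricks.as_strided(
        xp, shape=(n, cin, kh, kw, ho, wo),
        strides=(s0, s1, s2, s3, s2 * stride, s3 * stride), writeable=False)
    cols = windows.reshape(n, cin * kh * kw, ho * wo)  # contiguous copy
    w2 = w.data.reshape(f, -1)
    out_data = np.matmul(w2, cols).reshape(n, f, ho, wo)
    if b is not None:
        out_data += b.data.reshape(1, f, 1, 1)

    def backward(g):
        gf = g.reshape(n, f, ho * wo)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3)))
        # dW: batched (F, L) @ (L, CK); BLAS handles the transposed view
        dw = np.matmul(gf, cols.swapaxes(1, 2)).sum(axis=0)
        w._accum(dw.reshape(w.data.shape))
        dcols = np.matmul(w2.T, gf).reshape(n, cin, kh, kw, ho, wo)
        dxp = np.zeros_like(xp)
        for i in range(kh):
            for j in range(kw):
                dxp[:, :, i:i + ho * stride:stride,
                    j:j + wo * stride:stride] += dcols[:, :, i, j]
        x._accum(dxp[:, :, pad:dxp.shape[2] - pad, pad:dxp.shape[3] - pad]
                 if pad else dxp)

    parents = (x, w) if b is None else (x, w, b)
    return _node(out_data, parents, backward)


# -- modules ---------------------------------------------------------------

class Module:
    """Base class: parameter discovery, train/eval mode, state (de)serialization."""

    training: bool = True

    def parameters(self):
        out = []
        for v in self.__dict__.values():
            if isinstance(v, Tensor) and v.requires_grad:
                out.append(v)
            elif isinstance(v, Module):
                out.extend(v.parameters())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.parameters())
        return out

    def modules(self):
        out = [self]
        for v in self.__dict__.values():
            if isinstance(v, Module):
                out.extend(v.modules())
            elif isinstance(v, (list, tuple)):
                for item in v:
                    if isinstance(item, Module):
                        out.extend(item.modules())
        return out

    def train(self, mode: bool = True):
        for m in self.modules():
            m.training = mode
        return self

    def eval(self):
        return self.train(False)

    def n_parameters(self) -> int:
        return int(sum(p.data.size for p in self.parameters()))

    def state_arrays(self):
        """Flat list of all learnable and buffer arrays, in module order."""
        arrs = []
        for m in self.modules():
            for k, v in m.__dict__.items():
                if isinstance(v, Tensor) and v.requires_grad:
                    arrs.append((m, k, v.data))
                elif isinstance(v, np.ndarray) and k.startswith("running_"):
                    arrs.append((m, k, v))
        return arrs

    def get_state(self):
        return [a.copy() for _, _, a in self.state_arrays()]

    def set_state(self, arrays):
        slots = self.state_arrays()
        if len(slots) != len(arrays):
            raise ValueError("state length mismatch")
        for (m, k, _), new in zip(slots, arrays):
            v = getattr(m, k)
            if isinstance(v, Tensor):
                v.data = np.asarray(new, dtype=np.float32).reshape(v.data.shape)
            else:
                setattr(m, k, np.asarray(new, dtype=v.dtype).reshape(v.shape))

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def _he_init(rng, shape, fan_in):
    return (rng.standard_normal(shape) * np.sqrt(2.0 / fan_in)).astype(np.float32)


class Conv2d(Module):
    def __init__(self, cin, cout, k=3, stride=1, pad=None, rng=None, bias=True):
        rng = rng or np.random.default_rng(0)
        self.stride = stride
        self.pad = (k // 2) if pad is None else pad
        self.weight = Tensor(_he_init(rng, (cout, cin, k, k), cin * k * k),
                             requires_grad=True)
        self.bias = Tensor(np.zeros(cout, np.float32), requires_grad=True) if bias else None

    def forward(self, x):
        return conv2d(x, self.weight, self.bias, self.stride, self.pad)


class Linear(Module):
    def __init__(self, din, dout, rng=None):
        rng = rng or np.random.default_rng(0)
        self.weight = Tensor(_he_init(rng, (din, dout), din), requires_grad=True)
        self.bias = Tensor(np.zeros(dout, np.float32), requires_grad=True)

    def forward(self, x):
        return add(matmul(x, self.weight), self.bias)


class BatchNorm2d(Module):
    def __init__(self, channels, momentum=0.1, eps=1e-5):
        self.gamma = Tensor(np.ones(channels, np.float32), requires_grad=True)
        self.beta = Tensor(np.zeros(channels, np.float32), requires_grad=True)
        self.running_mean = np.zeros(channels, np.float32)
        self.running_var = np.ones(channels, np.float32)
        self.momentum = momentum
        self.eps = eps

    def forward(self, x):
        c = x.data.shape[1]
        if self.training:
            out, mu, var = batch_norm(x, self.gamma, self.beta, self.eps)
            self.running_mean = ((1 - self.momentum) * self.running_mean +
                                 self.momentum * mu)
            self.running_var = ((1 - self.momentum) * self.running_var +
                                self.momentum * var)
            return out
        mu = self.running_mean.reshape(1, c, 1, 1)
        inv = (1.0 / np.sqrt(self.running_var.reshape(1, c, 1, 1) + self.eps)
               ).astype(np.float32)
        scale = Tensor(self.gamma.data.reshape(1, c, 1, 1) * inv)
        shift = Tensor(self.beta.data.reshape(1, c, 1, 1) - mu * scale.data)
        # affine in eval mode, but keep gamma/beta out of the tape (frozen stats)
        return add(mul(x, scale), shift)


class Sequential(Module):
    def __init__(self, *layers):
        self.layers = list(layers)

    def forward(self, x):
        for layer in self.layers:
            x = layer(x) if isinstance(layer, Module) else layer(x)
        return x


class LeakyReLU(Module):
    def __init__(self, slope=0.1):
        self.slope = slope

    def forward(self, x):
        return leaky_relu(x, self.slope)


class Adam:
    """Adaptive-moment optimizer with bias correction."""

    def __init__(self, params, lr=1e-4, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, betas[0], betas[1], eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1 ** self.t)
            vhat = self.v[i] / (1 - self.b2 ** self.t)
            p.data -= (self.lr * mhat / (np.sqrt(vhat) + self.eps)).astype(np.float32)
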