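"""Minimal define-by-run autograd engine for 3D segmentation networks on CPU.

Implements exactly the operator set the segmentation networks need — 3D
convolution (strided, padded), transposed convolution with kernel == stride,
instance normalization, LeakyReLU, sigmoid, softmax, elementwise arithmetic
with broadcasting, reductions, and concatenation — together with a parameter
container, ``Module`` tree, state-dict (de)serialization, and SGD with
Nesterov momentum and weight decay.

Every operation is implemented with numpy and is bitwise deterministic: the
same weights and inputs always produce the same floats, which the training
loop relies on for reproducibility guarantees.
"""

from __future__ import annotations

import itertools
from contextlib import contextmanager

import numpy as np

__all__ = [
    "Tensor",
    "Parameter",
    "Module",
    "SGD",
    "no_grad",
    "tensor",
    "concat",
    "leaky_relu",
    "sigmoid",
    "softmax",
    "conv3d",
    "conv_transpose3d",
    "instance_norm",
    "softmax_cross_entropy",
]

_grad_enabled = True


@contextmanager
def no_grad():
    """Disable graph construction (inference mode)."""
    global _grad_enabled
    prev = _grad_enabled
    _grad_enabled = False
    try:
        yield
    finally:
        _grad_enabled = prev


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    if grad.shape == shape:
        return grad
    ndiff = grad.ndim - len(shape)
    if ndiff > 0:
        grad = grad.sum(axis=tuple(range(ndiff)))
    axes = tuple(i for i, s in enumerate(shape) if s == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad


class Tensor:
    """A numpy array with an optional gradient and backward closure."""

    __slots__ = ("data", "grad", "requires_grad", "_backward", "_parents")

    def __init__(self, data, requires_grad=False, parents=(), backward=None):
        self.data = np.asarray(data, dtype=np.float32)
        self.grad = None
        self.requires_grad = bool(requires_grad)
        self._parents = parents if _grad_enabled else ()
        self._backward = backward if _grad_enabled else None

    # -- graph ------------------------------------------------------------
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

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
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
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)

    def _accum(self, g: np.ndarray):
        if self.grad is None:
            self.grad = g.astype(np.float32, copy=True)
        else:
            self.grad += g

    # -- arithmetic -------------------------------------------------------
    def __add__(self, other):
        other = tensor(other)
        out = Tensor(self.data + other.data)

        def bwd(g):
            self._accum(_unbroadcast(g, self.data.shape))
            other._accum(_unbroadcast(g, other.data.shape))

        out._parents = (self, other) if _grad_enabled else ()
        out._backward = bwd if _grad_enabled else None
        return out

    __radd__ = __add__

    def __neg__(self):
        out = Tensor(-self.data)

        def bwd(g):
            self._accum(-g)

        out._parents = (self,) if _grad_enabled else ()
        out._backward = bwd if _grad_enabled else None
        return out

    def __sub__(self, other):
        return self + (-tensor(other))

    def __rsub__(self, other):
        return tensor(other) + (-self)

    def __mul__(self, other):
        other = tensor(other)
        out = Tensor(self.data * other.data)

        def bwd(g):
            self._accum(_unbroadcast(g * other.data, self.data.shape))
            other._accum(_unbroadcast(g * self.data, other.data.shape))

        out._parents = (self, other) if _grad_enabled else ()
        out._backward = bwd if _grad_enabled else None
        return out

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = tensor(other)
        out = Tensor(self.data / other.data)

        def bwd(g):
            self._accum(_unbroadcast(g / other.data, self.data.shape))
            other._accum(
                _unbroadcast(-g * self.data / (other.data**2), other.data.shape)
            )

        out._parents = (self, other) if _grad_enabled else ()
        out._backward = bwd if _grad_enabled else None
        return out

    def __rtruediv__(self, other):
        return tensor(other) / self

    # -- reductions -------------------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out = Tensor(self.data.sum(axis=axis, keepdims=keepdims))

        def bwd(g):
            if axis is None:
                self._accum(np.broadcast_to(g, self.data.shape).copy())
            else:
                if not keepdims:
                    g = np.expand_dims(g, axis)
                self._accum(np.broadcast_to(g, self.data.shape).copy())

        out._parents = (self,) if _grad_enabled else ()
        out._backward = bwd if _grad_enabled else None
        return out

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else np.prod(
            [self.data.shape[a] for a in np.atleast_1d(axis)]
        )
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / float(n))

    def max(self, axis, keepdims=False):
        m = self.data.max(axis=axis, keepdims=True)
        out = Tensor(m if keepdims else np.squeeze(m, axis=axis))

        def bwd(g):
            if not keepdims:
                g = np.expand_dims(g, axis)
            mask = (self.data == m).astype(np.float32)
            # ties share the incoming gradient equally
            mask /= np.maximum(mask.sum(axis=axis, keepdims=True), 1.0)
            self._accum(mask * g)

        out._parents = (self,) if _grad_enabled else ()
        out._backward = bwd if _grad_enabled else None
        return out

    def reshape(self, *shape):
        out = Tensor(self.data.reshape(*shape))

        def bwd(g):
            self._accum(g.reshape(self.data.shape))

        out._parents = (self,) if _grad_enabled else ()
        out._backward = bwd if _grad_enabled else None
        return out

    def __repr__(self):
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"


def tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(np.asarray(x, dtype=np.float32))


class Parameter(Tensor):
    """A trainable tensor."""

    def __init__(self, data):
        super().__init__(data, requires_grad=True)


# ---------------------------------------------------------------------------
# activations
# ---------------------------------------------------------------------------

def leaky_relu(x: Tensor, negative_slope: float = 0.01) -> Tensor:
    mask = x.data > 0
    out = Tensor(np.where(mask, x.data, negative_slope * x.data))

    def bwd(g):
        x._accum(np.where(mask, g, negative_slope * g))

    out._parents = (x,) if _grad_enabled else ()
    out._backward = bwd if _grad_enabled else None
    return out


def sigmoid(x: Tensor) -> Tensor:
    s = 1.0 / (1.0 + np.exp(-x.data))
    out = Tensor(s)

    def bwd(g):
        x._accum(g * s * (1.0 - s))

    out._parents = (x,) if _grad_enabled else ()
    out._backward = bwd if _grad_enabled else None
    return out


def softmax(x: Tensor, axis: int = 1) -> Tensor:
    z = x.data - x.data.max(axis=axis, keepdims=True)
    e = np.exp(z)
    s = e / e.sum(axis=axis, keepdims=True)
    out = Tensor(s)

    def bwd(g):
        dot = (g * s).sum(axis=axis, keepdims=True)
        x._accum(s * (g - dot))

    out._parents = (x,) if _grad_enabled else ()
    out._backward = bwd if _grad_enabled else None
    return out


def concat(tensors: list[Tensor], axis: int = 1) -> Tensor:
    out = Tensor(np.concatenate([t.data for t in tensors], axis=axis))
    sizes = [t.data.shape[axis] for t in tensors]
    offsets = np.cumsum([0] + sizes)

    def bwd(g):
        for t, lo, hi in zip(tensors, offsets[:-1], offsets[1:]):
            idx = [slice(None)] * g.ndim
            idx[axis] = slice(lo, hi)
            t._accum(g[tuple(idx)])

    out._parents = tuple(tensors) if _grad_enabled else ()
    out._backward = bwd if _grad_enabled else None
    return out


# ---------------------------------------------------------------------------
# convolution
# ---------------------------------------------------------------------------

def _triple(v):
    if np.isscalar(v):
        return (int(v),) * 3
    return tuple(int(a) for a in v)


# above this many elements the im2col matrix is not materialized and a
# memory-lean per-offset loop is used instead (large inference volumes)
_IM2COL_MAX_ELEMS = 1 << 26


def conv3d(x: Tensor, w: Tensor, b: Tensor | None = None,
           stride=(1, 1, 1), padding=None) -> Tensor:
    """3D cross-correlation, NCDHW layout.

    ``w`` has shape (C_out, C_in, kd, kh, kw). Default padding keeps odd
    kernels "same"-sized at stride 1. Small workloads run as one im2col
    matrix product (BLAS); very large ones fall back to a sum over kernel
    offsets of channel contractions, which keeps peak memory at the size of
    the output rather than a full im2col matrix.
    """
    sd, sh, sw = _triple(stride)
    kd, kh, kw = w.data.shape[2:]
    if padding is None:
        padding = (kd // 2, kh // 2, kw // 2)
    pd, ph, pw = _triple(padding)
    n, cin, d, h, wd = x.data.shape
    cout = w.data.shape[0]
    do = (d + 2 * pd - kd) // sd + 1
    ho = (h + 2 * ph - kh) // sh + 1
    wo = (wd + 2 * pw - kw) // sw + 1
    kvol = kd * kh * kw

    xp = np.pad(x.data, ((0, 0), (0, 0), (pd, pd), (ph, ph), (pw, pw)))
    offsets = list(itertools.product(range(kd), range(kh), range(kw)))
    use_im2col = n * cin * kvol * do * ho * wo <= _IM2COL_MAX_ELEMS

    if use_im2col:
        view = np.lib.stride_tricks.sliding_window_view(
            xp, (kd, kh, kw), axis=(2, 3, 4))[:, :, ::sd, ::sh, ::sw]
        # (n, cin*kvol, do*ho*wo): copy order keeps spatial blocks contiguous
        cols = np.ascontiguousarray(
            view.transpose(0, 1, 5, 6, 7, 2, 3, 4)
        ).reshape(n, cin * kvol, do * ho * wo)
        w2d = w.data.reshape(cout, cin * kvol)
        out_data = (w2d @ cols).reshape(n, cout, do, ho, wo)
    else:
        cols = None
        out_data = np.zeros((n, cout, do, ho, wo), dtype=np.float32)
        for i, j, k in offsets:
            xs = xp[:, :, i:i + sd * do:sd, j:j + sh * ho:sh,
                    k:k + sw * wo:sw]
            out_data += np.einsum("oc,ncdhw->nodhw", w.data[:, :, i, j, k],
                                  xs, optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(out_data)

    def bwd(g):
        g2d = g.reshape(n, cout, do * ho * wo)
        if cols is not None:
            gw = np.matmul(g2d, cols.transpose(0, 2, 1)).sum(axis=0)
            w._accum(gw.reshape(w.data.shape))
            w2d = w.data.reshape(cout, cin * kvol)
            gcols = np.matmul(w2d.T, g2d).reshape(
                n, cin, kd, kh, kw, do, ho, wo)
            gxp = np.zeros_like(xp)
            for i, j, k in offsets:
                gxp[:, :, i:i + sd * do:sd, j:j + sh * ho:sh,
                    k:k + sw * wo:sw] += gcols[:, :, i, j, k]
        else:
            gxp = np.zeros_like(xp)
            gw = np.zeros_like(w.data)
            for i, j, k in offsets:
                xs = xp[:, :, i:i + sd * do:sd, j:j + sh * ho:sh,
                        k:k + sw * wo:sw]
                gw[:, :, i, j, k] = np.einsum("nodhw,ncdhw->oc", g, xs,
                                              optimize=True)
                gxp[:, :, i:i + sd * do:sd, j:j + sh * ho:sh,
                    k:k + sw * wo:sw] += np.einsum(
                        "oc,nodhw->ncdhw", w.data[:, :, i, j, k], g,
                        optimize=True)
            w._accum(gw)
        x._accum(gxp[:, :, pd:pd + d, ph:ph + h, pw:pw + wd])
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    out._parents = parents if _grad_enabled else ()
    out._backward = bwd if _grad_enabled else None
    return out


def conv_transpose3d(x: Tensor, w: Tensor, b: Tensor | None = None,
                     stride=(2, 2, 2)) -> Tensor:
    """Transposed 3D convolution with kernel size equal to stride.

    With kernel == stride the output blocks do not overlap, so the op is an
    exact channel mixing + spatial upsampling: shape (N, C_out, D*sd, H*sh,
    W*sw). ``w`` has shape (C_in, C_out, sd, sh, sw).
    """
    sd, sh, sw = _triple(stride)
    assert w.data.shape[2:] == (sd, sh, sw), "kernel must equal stride"
    n, cin, d, h, wd = x.data.shape
    cout = w.data.shape[1]
    out_data = np.zeros((n, cout, d * sd, h * sh, wd * sw), dtype=np.float32)
    offsets = list(itertools.product(range(sd), range(sh), range(sw)))
    for i, j, k in offsets:
        out_data[:, :, i::sd, j::sh, k::sw] = np.einsum(
            "co,ncdhw->nodhw", w.data[:, :, i, j, k], x.data, optimize=True)
    if b is not None:
        out_data += b.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(out_data)

    def bwd(g):
        gw = np.zeros_like(w.data)
        gx = np.zeros_like(x.data)
        for i, j, k in offsets:
            gs = g[:, :, i::sd, j::sh, k::sw]
            gw[:, :, i, j, k] = np.einsum("nodhw,ncdhw->co", gs, x.data,
                                          optimize=True)
            gx += np.einsum("co,nodhw->ncdhw", w.data[:, :, i, j, k], gs,
                            optimize=True)
        w._accum(gw)
        x._accum(gx)
        if b is not None:
            b._accum(g.sum(axis=(0, 2, 3, 4)))

    parents = (x, w) if b is None else (x, w, b)
    out._parents = parents if _grad_enabled else ()
    out._backward = bwd if _grad_enabled else None
    return out


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor,
                  eps: float = 1e-5) -> Tensor:
    """Instance normalization over spatial axes, learnable affine per channel."""
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    gview = gamma.data.reshape(1, -1, 1, 1, 1)
    out = Tensor(xhat * gview + beta.data.reshape(1, -1, 1, 1, 1))

    def bwd(g):
        gamma._accum((g * xhat).sum(axis=(0, 2, 3, 4)))
        beta._accum(g.sum(axis=(0, 2, 3, 4)))
        gh = g * gview
        m1 = gh.mean(axis=axes, keepdims=True)
        m2 = (gh * xhat).mean(axis=axes, keepdims=True)
        x._accum(inv * (gh - m1 - xhat * m2))

    out._parents = (x, gamma, beta) if _grad_enabled else ()
    out._backward = bwd if _grad_enabled else None
    return out


def softmax_cross_entropy(logits: Tensor, target: np.ndarray) -> Tensor:
    """Mean cross-entropy under softmax; accepts soft per-class targets.

    ``target`` is a plain array of shape equal to the logits (per-voxel class
    distributions summing to 1).
    """
    if not np.all(np.isfinite(logits.data)):
        raise ValueError("non-finite logits in cross-entropy")
    t = np.asarray(target, dtype=np.float32)
    if t.shape != logits.data.shape:
        raise ValueError(
            f"target shape {t.shape} != logits shape {logits.data.shape}")
    z = logits.data - logits.data.max(axis=1, keepdims=True)
    logsumexp = np.log(np.exp(z).sum(axis=1, keepdims=True))
    logp = z - logsumexp
    n_vox = logits.data.size // logits.data.shape[1]
    loss = -(t * logp).sum() / n_vox
    out = Tensor(loss)

    def bwd(g):
        s = np.exp(logp)
        logits._accum(g * (s - t) / n_vox)

    out._parents = (logits,) if _grad_enabled else ()
    out._backward = bwd if _grad_enabled else None
    return out


# ---------------------------------------------------------------------------
# modules
# ---------------------------------------------------------------------------

class Module:
    """Base class: tracks Parameters via attribute discovery, like-for-like
    state dict save/load keyed by attribute path."""

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            key = f"{prefix}{name}"
            if isinstance(val, Parameter):
                yield key, val
            elif isinstance(val, Module):
                yield from val.named_parameters(prefix=key + ".")
            elif isinstance(val, (list, tuple)):
                for i, item in enumerate(val):
                    if isinstance(item, Module):
                        yield from item.named_parameters(prefix=f"{key}.{i}.")
                    elif isinstance(item, Parameter):
                        yield f"{key}.{i}", item

    def parameters(self) -> list[Parameter]:
        return [p for _, p in self.named_parameters()]

    def zero_grad(self):
        for p in self.parameters():
            p.grad = None

    def state_dict(self) -> dict[str, np.ndarray]:
        return {k: p.data.copy() for k, p in self.named_parameters()}

    def load_state_dict(self, state: dict[str, np.ndarray], strict: bool = True):
        own = dict(self.named_parameters())
        loaded, skipped = [], []
        for k, p in own.items():
            if k in state and state[k].shape == p.data.shape:
                p.data = np.asarray(state[k], dtype=np.float32).copy()
                loaded.append(k)
            else:
                skipped.append(k)
        extra = [k for k in state if k not in own]
        if strict and (skipped or extra):
            raise ValueError(
                f"state dict mismatch: missing/mismatched {skipped}, unexpected {extra}")
        return {"loaded": loaded, "skipped": skipped, "unexpected": extra}

    def count_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())

    def __call__(self, *args, **kwargs):
        return self.forward(*args, **kwargs)


def he_init(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    std = np.sqrt(2.0 / fan_in)
    return (rng.standard_normal(shape) * std).astype(np.float32)


class Conv3d(Module):
    def __init__(self, cin, cout, kernel=3, stride=1, rng=None, bias=True,
                 zero_init=False):
        k = _triple(kernel)
        self.stride = _triple(stride)
        fan_in = cin * int(np.prod(k))
        rng = rng or np.random.default_rng(0)
        if zero_init:
            self.weight = Parameter(np.zeros((cout, cin) + k, dtype=np.float32))
        else:
            self.weight = Parameter(he_init(rng, (cout, cin) + k, fan_in))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv3d(x, self.weight, self.bias, stride=self.stride)


class ConvTranspose3d(Module):
    def __init__(self, cin, cout, stride, rng=None, bias=True):
        s = _triple(stride)
        rng = rng or np.random.default_rng(0)
        self.stride = s
        self.weight = Parameter(he_init(rng, (cin, cout) + s, cin))
        self.bias = Parameter(np.zeros(cout, dtype=np.float32)) if bias else None

    def forward(self, x):
        return conv_transpose3d(x, self.weight, self.bias, stride=self.stride)


class InstanceNorm3d(Module):
    def __init__(self, channels, eps=1e-5):
        self.eps = eps
        self.gamma = Parameter(np.ones(channels, dtype=np.float32))
        self.beta = Parameter(np.zeros(channels, dtype=np.float32))

    def forward(self, x):
        return instance_norm(x, self.gamma, self.beta, self.eps)


class SGD:
    """SGD with Nesterov momentum and decoupled-from-loss L2 weight decay."""

    def __init__(self, params: list[Parameter], lr: float, momentum: float = 0.99,
                 weight_decay: float = 0.0, nesterov: bool = True):
        self.params = list(params)
        self.lr = lr
        self.momentum = momentum
        self.weight_decay = weight_decay
        self.nesterov = nesterov
        self._velocity = [np.zeros_like(p.data) for p in self.params]

    def step(self):
        for p, v in zip(self.params, self._velocity):
            if p.grad is None:
                continue
            g = p.grad
            if self.weight_decay:
                g = g + self.weight_decay * p.data
            v *= self.momentum
            v += g
            if self.nesterov:
                update = self.momentum * v + g
            else:
                update = v
            p.data -= self.lr * update

    def zero_grad(self):
        for p in self.params:
            p.grad = None
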