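"""Minimal reverse-mode automatic differentiation on NumPy arrays.

The package trains its sequence models on CPU with float64 arrays, so a
small tape-based engine is sufficient: a :class:`Tensor` records its
parents together with vector-Jacobian closures, and ``backward`` walks the
tape in reverse topological order.  Only the operations the models need are
provided; each custom operation (causal FFT convolution, depthwise causal
convolution, layer normalisation, masked cross-entropy) carries an
analytically derived adjoint that is verified against finite differences in
the test suite.
"""

from __future__ import annotations

import numpy as np
from scipy import fft as sfft

__all__ = [
    "Tensor",
    "add",
    "sub",
    "mul",
    "matmul",
    "embedding",
    "layer_norm",
    "gelu",
    "relu",
    "sin",
    "exp",
    "softplus",
    "scale",
    "mean_axis",
    "depthwise_causal_conv",
    "conv1d_causal",
    "causal_fft_conv",
    "masked_cross_entropy",
    "softmax_cross_entropy",
    "Adam",
    "clip_global_norm",
]


class Tensor:
    """Array node in the computation tape."""

    __slots__ = ("data", "grad", "parents", "requires_grad")

    def __init__(self, data, requires_grad: bool = False, parents=()):
        self.data = np.asarray(data, dtype=np.float64)
        self.grad = None
        self.parents = tuple(parents)  # (Tensor, vjp) pairs
        self.requires_grad = bool(requires_grad) or any(
            p.requires_grad for p, _ in parents
        )

    @property
    def shape(self):
        return self.data.shape

    def __repr__(self):  # pragma: no cover - debugging aid
        return f"Tensor(shape={self.data.shape}, grad={self.grad is not None})"

    # operator sugar ------------------------------------------------------
    def __add__(self, other):
        return add(self, _as_tensor(other))

    def __radd__(self, other):
        return add(_as_tensor(other), self)

    def __sub__(self, other):
        return sub(self, _as_tensor(other))

    def __mul__(self, other):
        return mul(self, _as_tensor(other))

    def __rmul__(self, other):
        return mul(_as_tensor(other), self)

    def __matmul__(self, other):
        return matmul(self, other)

    def backward(self):
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        order: list[Tensor] = []
        seen: set[int] = set()
        stack = [(self, False)]
        while stack:  # iterative DFS; deep stacks occur for long tapes
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for parent, _ in node.parents:
                stack.append((parent, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            g = node.grad
            if g is None:
                continue
            for parent, vjp in node.parents:
                if not parent.requires_grad:
                    continue
                contrib = vjp(g)
                if parent.grad is None:
                    parent.grad = contrib.copy()
                else:
                    parent.grad += contrib


def _as_tensor(x) -> Tensor:
    return x if isinstance(x, Tensor) else Tensor(x)


def _unbroadcast(g: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum ``g`` down to ``shape`` to undo NumPy broadcasting."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for axis, dim in enumerate(shape):
        if dim == 1 and g.shape[axis] != 1:
            g = g.sum(axis=axis, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# elementwise / linear algebra


def add(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    out = a.data + b.data
    return Tensor(
        out,
        parents=(
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(g, b.data.shape)),
        ),
    )


def sub(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(
        a.data - b.data,
        parents=(
            (a, lambda g: _unbroadcast(g, a.data.shape)),
            (b, lambda g: _unbroadcast(-g, b.data.shape)),
        ),
    )


def mul(a: Tensor, b: Tensor) -> Tensor:
    a, b = _as_tensor(a), _as_tensor(b)
    return Tensor(
        a.data * b.data,
        parents=(
            (a, lambda g: _unbroadcast(g * b.data, a.data.shape)),
            (b, lambda g: _unbroadcast(g * a.data, b.data.shape)),
        ),
    )


def scale(a: Tensor, c: float) -> Tensor:
    a = _as_tensor(a)
    return Tensor(a.data * c, parents=((a, lambda g: g * c),))


def matmul(a: Tensor, b: Tensor) -> Tensor:
    """``a [..., m, k] @ b [k, n]`` with a 2-D weight on the right."""
    a, b = _as_tensor(a), _as_tensor(b)
    if b.data.ndim != 2:
        raise ValueError("matmul expects a 2-D right operand")
    out = a.data @ b.data

    def da(g):
        return g @ b.data.T

    def db(g):
        k = a.data.shape[-1]
        return a.data.reshape(-1, k).T @ g.reshape(-1, g.shape[-1])

    return Tensor(out, parents=((a, da), (b, db)))


def embedding(weight: Tensor, ids: np.ndarray) -> Tensor:
    """Row lookup ``weight[ids]`` for integer ``ids`` of any shape."""
    ids = np.asarray(ids)
    out = weight.data[ids]

    def dw(g):
        grad = np.zeros_like(weight.data)
        np.add.at(grad, ids.reshape(-1), g.reshape(-1, g.shape[-1]))
        return grad

    return Tensor(out, parents=((weight, dw),))


def layer_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    mu = x.data.mean(axis=-1, keepdims=True)
    var = x.data.var(axis=-1, keepdims=True)
    inv = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv
    out = xhat * gamma.data + beta.data

    def dx(g):
        gx = g * gamma.data
        m1 = gx.mean(axis=-1, keepdims=True)
        m2 = (gx * xhat).mean(axis=-1, keepdims=True)
        return inv * (gx - m1 - xhat * m2)

    def dgamma(g):
        return (g * xhat).reshape(-1, x.data.shape[-1]).sum(axis=0)

    def dbeta(g):
        return g.reshape(-1, x.data.shape[-1]).sum(axis=0)

    return Tensor(out, parents=((x, dx), (gamma, dgamma), (beta, dbeta)))


_GELU_C = np.sqrt(2.0 / np.pi)


def gelu(x: Tensor) -> Tensor:
    """tanh-approximated GELU."""
    xd = x.data
    inner = _GELU_C * (xd + 0.044715 * xd**3)
    t = np.tanh(inner)
    out = 0.5 * xd * (1.0 + t)

    def dx(g):
        dinner = _GELU_C * (1.0 + 3 * 0.044715 * xd**2)
        return g * (0.5 * (1.0 + t) + 0.5 * xd * (1.0 - t**2) * dinner)

    return Tensor(out, parents=((x, dx),))


def relu(x: Tensor) -> Tensor:
    mask = x.data > 0
    return Tensor(np.where(mask, x.data, 0.0), parents=((x, lambda g: g * mask),))


def sin(x: Tensor) -> Tensor:
    return Tensor(np.sin(x.data), parents=((x, lambda g: g * np.cos(x.data)),))


def exp(x: Tensor) -> Tensor:
    out = np.exp(x.data)
    return Tensor(out, parents=((x, lambda g: g * out),))


def softplus(x: Tensor) -> Tensor:
    out = np.logaddexp(0.0, x.data)
    sig = 1.0 / (1.0 + np.exp(-x.data))
    return Tensor(out, parents=((x, lambda g: g * sig),))


def reshape(x: Tensor, shape: tuple) -> Tensor:
    orig = x.data.shape
    return Tensor(x.data.reshape(shape), parents=((x, lambda g: g.reshape(orig)),))


def mean_axis(x: Tensor, axis: int) -> Tensor:
    n = x.data.shape[axis]
    out = x.data.mean(axis=axis)

    def dx(g):
        return np.repeat(np.expand_dims(g, axis), n, axis=axis) / n

    return Tensor(out, parents=((x, dx),))


# ---------------------------------------------------------------------------
# convolutions


def _shift_down(x: np.ndarray, k: int) -> np.ndarray:
    """x[:, t-k, :] with zeros for t < k (axis 1)."""
    if k == 0:
        return x
    out = np.zeros_like(x)
    out[:, k:] = x[:, :-k]
    return out


def _shift_up(x: np.ndarray, k: int) -> np.ndarray:
    if k == 0:
        return x
    out = np.zeros_like(x)
    out[:, :-k] = x[:, k:]
    return out


def depthwise_causal_conv(x: Tensor, kernel: Tensor) -> Tensor:
    """Per-channel causal FIR filter.

    ``x`` is [B, L, D]; ``kernel`` is [W, D] with lag-0 tap first, so
    ``y[b, t, d] = sum_w kernel[w, d] * x[b, t - w, d]``.
    """
    xd, kd = x.data, kernel.data
    width = kd.shape[0]
    out = np.zeros_like(xd)
    for w in range(width):
        out += kd[w] * _shift_down(xd, w)

    def dx(g):
        grad = np.zeros_like(xd)
        for w in range(width):
            grad += kd[w] * _shift_up(g, w)
        return grad

    def dk(g):
        grad = np.zeros_like(kd)
        for w in range(width):
            grad[w] = (_shift_down(xd, w) * g).sum(axis=(0, 1))
        return grad

    return Tensor(out, parents=((x, dx), (kernel, dk)))


def conv1d_causal(x: Tensor, kernel: Tensor) -> Tensor:
    """Dense causal 1-D convolution: x [B, L, Cin], kernel [W, Cin, Cout]."""
    xd, kd = x.data, kernel.data
    width = kd.shape[0]
    out = np.zeros(xd.shape[:2] + (kd.shape[2],))
    for w in range(width):
        out += _shift_down(xd, w) @ kd[w]

    def dx(g):
        grad = np.zeros_like(xd)
        for w in range(width):
            grad += _shift_up(g @ kd[w].T, w)
        return grad

    def dk(g):
        grad = np.zeros_like(kd)
        g2 = g.reshape(-1, g.shape[-1])
        for w in range(width):
            grad[w] = _shift_down(xd, w).reshape(-1, xd.shape[-1]).T @ g2
        return grad

    return Tensor(out, parents=((x, dx), (kernel, dk)))


def _cconv(a: np.ndarray, b: np.ndarray, length: int) -> np.ndarray:
    """Causal (lower-triangular Toeplitz) convolution along axis 1 via FFT.

    ``a`` is [B, L, D] (or [L, D]); ``b`` broadcasts against it.  Zero-pads
    to at least 2L-1 so the circular convolution equals the linear one.
    """
    n = sfft.next_fast_len(2 * length - 1, real=True)
    fa = sfft.rfft(a, n=n, axis=-2)
    fb = sfft.rfft(b, n=n, axis=-2)
    full = sfft.irfft(fa * fb, n=n, axis=-2)
    return full[..., :length, :]


def causal_fft_conv(u: Tensor, h: Tensor) -> Tensor:
    """Causal long convolution ``y[t] = sum_{s<=t} h[t-s] u[s]`` per channel.

    ``u`` is [B, L, D] (or [L, D]); ``h`` is [L, D] shared across the batch.
    Equivalent to multiplying each channel by the lower-triangular Toeplitz
    matrix of its filter, computed in O(L log L) via zero-padded real FFTs.
    """
    ud, hd = u.data, h.data
    if ud.shape[-2:] != hd.shape[-2:]:
        raise ValueError(
            f"filter shape {hd.shape} does not match input shape {ud.shape}"
        )
    L = ud.shape[-2]
    out = _cconv(ud, hd, L)

    def du(g):
        # adjoint of causal convolution is causal correlation:
        # du[s] = sum_{t>=s} h[t-s] g[t] = reverse(cconv(reverse(g), h))
        return _cconv(g[..., ::-1, :], hd, L)[..., ::-1, :]

    def dh(g):
        grad = _cconv(g[..., ::-1, :], ud, L)[..., ::-1, :]
        if grad.ndim > hd.ndim:  # batch dimension was broadcast
            grad = grad.sum(axis=tuple(range(grad.ndim - hd.ndim)))
        return grad

    return Tensor(out, parents=((u, du), (h, dh)))


# ---------------------------------------------------------------------------
# losses


def masked_cross_entropy(logits: Tensor, targets: np.ndarray, mask: np.ndarray) -> Tensor:
    """Mean cross-entropy over positions where ``mask`` is true.

    ``logits`` is [..., V]; ``targets`` integer class ids of matching leading
    shape; ``mask`` boolean of the same leading shape.
    """
    ld = logits.data
    targets = np.asarray(targets)
    mask = np.asarray(mask, dtype=bool)
    count = int(mask.sum())
    if count == 0:
        raise ValueError("masked_cross_entropy: no unmasked positions")
    m = ld.max(axis=-1, keepdims=True)
    z = ld - m
    lse = np.log(np.exp(z).sum(axis=-1, keepdims=True))
    logp = z - lse
    picked = np.take_along_axis(logp, targets[..., None], axis=-1)[..., 0]
    loss = -(picked * mask).sum() / count

    def dlogits(g):
        soft = np.exp(logp)
        onehot = np.zeros_like(ld)
        np.put_along_axis(onehot, targets[..., None], 1.0, axis=-1)
        return g * (soft - onehot) * mask[..., None] / count

    return Tensor(loss, parents=((logits, dlogits),))


def softmax_cross_entropy(logits: Tensor, targets: np.ndarray) -> Tensor:
    """Mean cross-entropy over all rows (classification head helper)."""
    mask = np.ones(np.asarray(targets).shape, dtype=bool)
    return masked_cross_entropy(logits, targets, mask)


# ---------------------------------------------------------------------------
# optimisation


class Adam:
    """Adaptive-moment gradient descent with bias correction."""

    def __init__(self, params, lr: float = 6e-4, betas=(0.9, 0.999), eps: float = 1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None

    def step(self) -> None:
        self.t += 1
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            mhat = self.m[i] / (1 - self.b1**self.t)
            vhat = self.v[i] / (1 - self.b2**self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def state_dict(self) -> dict:
        return {"t": self.t, "m": self.m, "v": self.v}


def clip_global_norm(params, max_norm: float) -> float:
    """Scale all gradients so their joint L2 norm is at most ``max_norm``."""
    total = 0.0
    for p in params:
        if p.grad is not None:
            total += float((p.grad**2).sum())
    norm = np.sqrt(total)
    if norm > max_norm and norm > 0:
        factor = max_norm / norm
        for p in params:
            if p.grad is not None:
                p.grad *= factor
    return norm
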