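"""Minimal reverse-mode automatic differentiation on NumPy arrays.

Implements exactly the operator set needed by the attention 3D U-Net:
3D convolution (kernel 1 or 3, stride 1 or 2, zero padding k//2), nearest
neighbour x2 upsampling, instance normalization, leaky ReLU, sigmoid, channel
concatenation, broadcast multiply/add, global average pooling, dense layers,
and fused segmentation/classification losses.  Gradients are checked against
central finite differences in the test suite.

Arrays keep their input dtype, so float64 can be used for gradient checking
while the network itself runs in float32.
"""

from __future__ import annotations

import numpy as np

__all__ = [
    "Tensor",
    "conv3d",
    "upsample_nearest2",
    "instance_norm",
    "leaky_relu",
    "sigmoid",
    "concat",
    "add",
    "mul",
    "add_n",
    "global_avg_pool",
    "dense",
    "bce_mean",
    "soft_jaccard",
    "Adam",
]


class Tensor:
    """An array node in the computation tape."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad", "name")

    def __init__(self, data, parents=(), backward=None, requires_grad=False, name=""):
        self.data = np.asarray(data)
        self.grad = None
        self._parents = parents
        self._backward = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)
        self.name = name

    @property
    def shape(self):
        return self.data.shape

    def _accumulate(self, g):
        if self.grad is None:
            self.grad = np.zeros_like(self.data)
        self.grad += g

    def backward(self):
        if self.data.ndim != 0 and self.data.size != 1:
            raise ValueError("backward() requires a scalar output")
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
            for p in node._parents:
                if id(p) not in visited:
                    stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(topo):
            if node._backward is not None and node.requires_grad:
                node._backward()

    # -- scalar arithmetic used to combine losses --------------------------
    def __add__(self, other):
        other = other if isinstance(other, Tensor) else Tensor(np.asarray(other, self.data.dtype))
        out = Tensor(self.data + other.data, (self, other))

        def bw():
            self._accumulate(_unbroadcast(out.grad, self.data.shape))
            other._accumulate(_unbroadcast(out.grad, other.data.shape))

        out._backward = bw
        return out

    __radd__ = __add__

    def __mul__(self, other):
        if isinstance(other, Tensor):
            return mul(self, other)
        out = Tensor(self.data * other, (self,))

        def bw():
            self._accumulate(out.grad * other)

        out._backward = bw
        return out

    __rmul__ = __mul__

    def __neg__(self):
        return self * -1.0

    def __sub__(self, other):
        return self + (-other if isinstance(other, Tensor) else -np.asarray(other))

    def __rsub__(self, other):
        return (-self) + other

    def item(self):
        return float(self.data)


def _unbroadcast(g, shape):
    """Sum gradient ``g`` down to ``shape`` (inverse of NumPy broadcasting)."""
    while g.ndim > len(shape):
        g = g.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and g.shape[ax] != 1:
            g = g.sum(axis=ax, keepdims=True)
    return g


# ---------------------------------------------------------------------------
# Neural-network operators
# ---------------------------------------------------------------------------

def conv3d(x: Tensor, w: Tensor, b: Tensor, stride: int = 1) -> Tensor:
    """3D convolution, NCDHW layout, zero padding k//2 ('same' for stride 1).

    ``w`` has shape (C_out, C_in, k, k, k) with k in {1, 3}.
    """
    k = w.shape[2]
    p = k // 2
    s = stride
    N, C, D, H, W = x.data.shape
    xp = np.pad(x.data, ((0, 0), (0, 0), (p, p), (p, p), (p, p))) if p else x.data
    Do = (D + 2 * p - k) // s + 1
    Ho = (H + 2 * p - k) // s + 1
    Wo = (W + 2 * p - k) // s + 1
    Cout = w.shape[0]
    out = np.zeros((N, Cout, Do, Ho, Wo), dtype=x.data.dtype)
    for dz in range(k):
        for dy in range(k):
            for dx in range(k):
                xs = xp[:, :, dz::s, dy::s, dx::s][:, :, :Do, :Ho, :Wo]
                out += np.einsum("oc,ncdhw->nodhw", w.data[:, :, dz, dy, dx], xs,
                                 optimize=True)
    out += b.data[None, :, None, None, None]
    res = Tensor(out, (x, w, b))

    def bw():
        g = res.grad
        if x.requires_grad:
            gxp = np.zeros_like(xp)
        for dz in range(k):
            for dy in range(k):
                for dx in range(k):
                    xs = xp[:, :, dz::s, dy::s, dx::s][:, :, :Do, :Ho, :Wo]
                    if w.requires_grad:
                        gw = np.einsum("nodhw,ncdhw->oc", g, xs, optimize=True)
                        if w.grad is None:
                            w.grad = np.zeros_like(w.data)
                        w.grad[:, :, dz, dy, dx] += gw
                    if x.requires_grad:
                        gxp[:, :, dz::s, dy::s, dx::s][:, :, :Do, :Ho, :Wo] += np.einsum(
                            "oc,nodhw->ncdhw", w.data[:, :, dz, dy, dx], g, optimize=True
                        )
        if b.requires_grad:
            b._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            x._accumulate(gxp[:, :, p:p + D, p:p + H, p:p + W] if p else gxp)

    res._backward = bw
    return res


def upsample_nearest2(x: Tensor) -> Tensor:
    """Nearest-neighbour upsampling by a factor of 2 along all spatial axes."""
    y = x.data.repeat(2, axis=2).repeat(2, axis=3).repeat(2, axis=4)
    res = Tensor(y, (x,))

    def bw():
        N, C, D, H, W = x.data.shape
        g = res.grad.reshape(N, C, D, 2, H, 2, W, 2).sum(axis=(3, 5, 7))
        x._accumulate(g)

    res._backward = bw
    return res


def instance_norm(x: Tensor, gamma: Tensor, beta: Tensor, eps: float = 1e-5) -> Tensor:
    """Per-sample, per-channel normalization over the spatial axes."""
    axes = (2, 3, 4)
    mu = x.data.mean(axis=axes, keepdims=True)
    var = x.data.var(axis=axes, keepdims=True)
    inv_std = 1.0 / np.sqrt(var + eps)
    xhat = (x.data - mu) * inv_std
    gamma_b = gamma.data[None, :, None, None, None]
    res = Tensor(gamma_b * xhat + beta.data[None, :, None, None, None], (x, gamma, beta))

    def bw():
        g = res.grad
        if gamma.requires_grad:
            gamma._accumulate((g * xhat).sum(axis=(0, 2, 3, 4)))
        if beta.requires_grad:
            beta._accumulate(g.sum(axis=(0, 2, 3, 4)))
        if x.requires_grad:
            dxhat = g * gamma_b
            m1 = dxhat.mean(axis=axes, keepdims=True)
            m2 = (dxhat * xhat).mean(axis=axes, keepdims=True)
            x._accumulate(inv_std * (dxhat - m1 - xhat * m2))

    res._backward = bw
    return res


def leaky_relu(x: Tensor, slope: float = 0.01) -> Tensor:
    pos = x.data > 0
    res = Tensor(np.where(pos, x.data, slope * x.data), (x,))

    def bw():
        x._accumulate(np.where(pos, res.grad, slope * res.grad))

    res._backward = bw
    return res


def sigmoid(x: Tensor) -> Tensor:
    y = 1.0 / (1.0 + np.exp(-np.clip(x.data, -60.0, 60.0)))
    res = Tensor(y, (x,))

    def bw():
        x._accumulate(res.grad * y * (1.0 - y))

    res._backward = bw
    return res


def concat(a: Tensor, b: Tensor, axis: int = 1) -> Tensor:
    res = Tensor(np.concatenate([a.data, b.data], axis=axis), (a, b))
    na = a.data.shape[axis]

    def bw():
        ga, gb = np.split(res.grad, [na], axis=axis)
        if a.requires_grad:
            a._accumulate(ga)
        if b.requires_grad:
            b._accumulate(gb)

    res._backward = bw
    return res


def add(a: Tensor, b: Tensor) -> Tensor:
    return a + b


def mul(a: Tensor, b: Tensor) -> Tensor:
    """Elementwise multiply with NumPy broadcasting (used by attention gates)."""
    res = Tensor(a.data * b.data, (a, b))

    def bw():
        if a.requires_grad:
            a._accumulate(_unbroadcast(res.grad * b.data, a.data.shape))
        if b.requires_grad:
            b._accumulate(_unbroadcast(res.grad * a.data, b.data.shape))

    res._backward = bw
    return res


def add_n(tensors) -> Tensor:
    out = tensors[0]
    for t in tensors[1:]:
        out = out + t
    return out


def global_avg_pool(x: Tensor) -> Tensor:
    """(N, C, D, H, W) -> (N, C) spatial mean."""
    res = Tensor(x.data.mean(axis=(2, 3, 4)), (x,))

    def bw():
        N, C, D, H, W = x.data.shape
        g = res.grad[:, :, None, None, None] / (D * H * W)
        x._accumulate(np.broadcast_to(g, x.data.shape).copy())

    res._backward = bw
    return res


def dense(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """(N, C_in) @ (C_in, C_out) + bias."""
    res = Tensor(x.data @ w.data + b.data, (x, w, b))

    def bw():
        g = res.grad
        if x.requires_grad:
            x._accumulate(g @ w.data.T)
        if w.requires_grad:
            w._accumulate(x.data.T @ g)
        if b.requires_grad:
            b._accumulate(g.sum(axis=0))

    res._backward = bw
    return res


# ---------------------------------------------------------------------------
# Losses
# ---------------------------------------------------------------------------

def bce_mean(pred: Tensor, target: np.ndarray, eps: float = 1e-7) -> Tensor:
    """Mean binary cross-entropy of probabilities against a 0/1 target.

    Probabilities are clipped to [eps, 1-eps]; the gradient is zero at
    clipped entries.
    """
    t = np.asarray(target, dtype=pred.data.dtype)
    inside = (pred.data > eps) & (pred.data < 1.0 - eps)
    p = np.clip(pred.data, eps, 1.0 - eps)
    loss = -(t * np.log(p) + (1.0 - t) * np.log(1.0 - p)).mean()
    res = Tensor(np.asarray(loss, dtype=pred.data.dtype), (pred,))

    def bw():
        g = res.grad * (p - t) / (p * (1.0 - p)) / p.size
        pred._accumulate(np.where(inside, g, 0.0))

    res._backward = bw
    return res


def soft_jaccard(pred: Tensor, target: np.ndarray, eps: float = 1e-6) -> Tensor:
    """Soft Jaccard index of a probability grid against a 0/1 target.

    J = (sum(p*t) + eps) / (sum(p) + sum(t) - sum(p*t) + eps); the empty/empty
    case evaluates to 1 by the eps-smoothing convention.
    """
    t = np.asarray(target, dtype=pred.data.dtype)
    inter = float((pred.data * t).sum())
    union = float(pred.data.sum() + t.sum() - inter)
    num, den = inter + eps, union + eps
    res = Tensor(np.asarray(num / den, dtype=pred.data.dtype), (pred,))

    def bw():
        g = res.grad * (t * den - num * (1.0 - t)) / (den * den)
        pred._accumulate(g)

    res._backward = bw
    return res


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adam with bias correction; operates in-place on parameter tensors."""

    def __init__(self, params, lr=1e-3, betas=(0.9, 0.999), eps=1e-8):
        self.params = list(params)
        self.lr = lr
        self.b1, self.b2 = betas
        self.eps = eps
        self.t = 0
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]

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
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)
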