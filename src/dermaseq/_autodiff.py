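"""Compact reverse-mode automatic differentiation over numpy arrays.

The training backend of the hybrid classifier: a dynamically built
computation graph of :class:`Tensor` nodes with exactly the operations
the architecture needs — matmul, broadcasting add/mul, the three
activations, batched valid convolution, strided max pooling, dropout,
slicing/concatenation and a softmax cross-entropy head — plus an Adam
optimizer.  Everything runs in float64 on one CPU and is deterministic
given the seeds, which keeps training histories exactly reproducible.

Forward semantics of the layer ops are pinned against the readable
reference implementations in :mod:`dermaseq.neural_reference`;
gradients are checked numerically in the test suite.
"""

from __future__ import annotations

import numpy as np
from numpy.lib.stride_tricks import sliding_window_view

__all__ = ["Tensor", "concat", "conv2d", "max_pool2d", "dropout",
           "softmax_cross_entropy", "softmax_probs", "Adam"]


def _unbroadcast(grad: np.ndarray, shape: tuple) -> np.ndarray:
    """Sum `grad` down to `shape` (inverse of numpy broadcasting)."""
    while grad.ndim > len(shape):
        grad = grad.sum(axis=0)
    for ax, n in enumerate(shape):
        if n == 1 and grad.shape[ax] != 1:
            grad = grad.sum(axis=ax, keepdims=True)
    return grad


class Tensor:
    """A node of the computation graph."""

    __slots__ = ("data", "grad", "requires_grad", "_parents", "_backward")

    def __init__(self, data, requires_grad: bool = False,
                 parents=(), backward=None):
        self.data = np.asarray(data, dtype=float)
        self.requires_grad = requires_grad or any(
            p.requires_grad for p in parents)
        self.grad = None
        self._parents = parents
        self._backward = backward

    @property
    def shape(self):
        return self.data.shape

    # ---- graph construction helpers -------------------------------------

    @staticmethod
    def _lift(x) -> "Tensor":
        return x if isinstance(x, Tensor) else Tensor(x)

    def __add__(self, other):
        other = self._lift(other)
        out = Tensor(self.data + other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g, self.data.shape),
                    _unbroadcast(g, other.data.shape))
        out._backward = backward
        return out

    __radd__ = __add__

    def __mul__(self, other):
        other = self._lift(other)
        out = Tensor(self.data * other.data, parents=(self, other))

        def backward(g):
            return (_unbroadcast(g * other.data, self.data.shape),
                    _unbroadcast(g * self.data, other.data.shape))
        out._backward = backward
        return out

    __rmul__ = __mul__

    def __sub__(self, other):
        return self + (self._lift(other) * -1.0)

    def matmul(self, other: "Tensor") -> "Tensor":
        other = self._lift(other)
        out = Tensor(self.data @ other.data, parents=(self, other))

        def backward(g):
            a, b = self.data, other.data
            ga = g @ np.swapaxes(b, -1, -2)
            gb = np.swapaxes(a, -1, -2) @ g
            return (_unbroadcast(ga, a.shape), _unbroadcast(gb, b.shape))
        out._backward = backward
        return out

    __matmul__ = matmul

    def reshape(self, *shape) -> "Tensor":
        out = Tensor(self.data.reshape(*shape), parents=(self,))
        out._backward = lambda g: (g.reshape(self.data.shape),)
        return out

    def __getitem__(self, key) -> "Tensor":
        out = Tensor(self.data[key], parents=(self,))

        def backward(g):
            full = np.zeros_like(self.data)
            np.add.at(full, key, g)
            return (full,)
        out._backward = backward
        return out

    def sum(self) -> "Tensor":
        out = Tensor(self.data.sum(), parents=(self,))
        out._backward = lambda g: (np.broadcast_to(g, self.data.shape).copy(),)
        return out

    def relu(self) -> "Tensor":
        out = Tensor(np.maximum(0.0, self.data), parents=(self,))
        out._backward = lambda g: (g * (self.data > 0),)
        return out

    def sigmoid(self) -> "Tensor":
        s = 1.0 / (1.0 + np.exp(-self.data))
        out = Tensor(s, parents=(self,))
        out._backward = lambda g: (g * s * (1.0 - s),)
        return out

    def tanh(self) -> "Tensor":
        t = np.tanh(self.data)
        out = Tensor(t, parents=(self,))
        out._backward = lambda g: (g * (1.0 - t * t),)
        return out

    # ---- backpropagation -------------------------------------------------

    def backward(self) -> None:
        """Accumulate gradients of this (scalar) node into the graph."""
        if self.data.size != 1:
            raise ValueError("backward() requires a scalar loss")
        topo, seen = [], set()

        def visit(t: "Tensor"):
            if id(t) in seen or not t.requires_grad:
                return
            seen.add(id(t))
            for p in t._parents:
                visit(p)
            topo.append(t)
        visit(self)

        grads = {id(self): np.ones_like(self.data)}
        for t in reversed(topo):
            g = grads.pop(id(t), None)
            if g is None:
                continue
            if not t._parents:       # leaf
                t.grad = g if t.grad is None else t.grad + g
                continue
            for p, pg in zip(t._parents, t._backward(g)):
                if not p.requires_grad:
                    continue
                if id(p) in grads:
                    grads[id(p)] = grads[id(p)] + pg
                else:
                    grads[id(p)] = pg


def concat(tensors: list[Tensor], axis: int) -> Tensor:
    parts = [Tensor._lift(t) for t in tensors]
    out = Tensor(np.concatenate([p.data for p in parts], axis=axis),
                 parents=tuple(parts))
    sizes = [p.data.shape[axis] for p in parts]
    splits = np.cumsum(sizes)[:-1]
    out._backward = lambda g: tuple(np.split(g, splits, axis=axis))
    return out


def conv2d(x: Tensor, w: Tensor, b: Tensor) -> Tensor:
    """Batched valid cross-correlation.

    x: (B, H, W, Cin); w: (kh, kw, Cin, Cout); b: (Cout,).
    Output (B, H-kh+1, W-kw+1, Cout), matching
    :func:`dermaseq.neural_reference.conv2d_valid` per channel pair.
    """
    B, H, W, Cin = x.data.shape
    kh, kw, cin, Cout = w.data.shape
    if cin != Cin:
        raise ValueError(f"kernel expects {cin} input channels, got {Cin}")
    if kh > H or kw > W:
        raise ValueError(f"kernel {w.data.shape[:2]} larger than input {(H, W)}")
    oh, ow = H - kh + 1, W - kw + 1
    win = sliding_window_view(x.data, (kh, kw), axis=(1, 2))   # (B,oh,ow,Cin,kh,kw)
    cols = win.transpose(0, 1, 2, 4, 5, 3).reshape(B * oh * ow, kh * kw * Cin)
    wmat = w.data.reshape(kh * kw * Cin, Cout)
    out_data = (cols @ wmat + b.data).reshape(B, oh, ow, Cout)
    out = Tensor(out_data, parents=(x, w, b))

    def backward(g):
        gflat = g.reshape(B * oh * ow, Cout)
        gw = (cols.T @ gflat).reshape(kh, kw, Cin, Cout)
        gb = gflat.sum(axis=0)
        gcols = (gflat @ wmat.T).reshape(B, oh, ow, kh, kw, Cin)
        gx = np.zeros((B, H, W, Cin))
        for m in range(kh):
            for n in range(kw):
                gx[:, m:m + oh, n:n + ow, :] += gcols[:, :, :, m, n, :]
        return (gx, gw, gb)
    out._backward = backward
    return out


def max_pool2d(x: Tensor, window: tuple = (2, 2), stride: int = 2) -> Tensor:
    """Strided max pooling over (B, H, W, C); partial windows dropped."""
    k, l = window
    B, H, W, C = x.data.shape
    if k > H or l > W:
        raise ValueError(f"pool window {window} exceeds input {(H, W)}")
    win = sliding_window_view(x.data, (k, l), axis=(1, 2))[:, ::stride, ::stride]
    out_data = win.max(axis=(-2, -1))             # (B, oh, ow, C)
    _, oh, ow, _ = out_data.shape
    out = Tensor(out_data, parents=(x,))

    def backward(g):
        arg = win.reshape(B, oh, ow, C, k * l).argmax(axis=-1)
        bi, ii, jj, ci = np.indices((B, oh, ow, C), sparse=False)
        rows = ii * stride + arg // l
        cols = jj * stride + arg % l
        gx = np.zeros((B, H, W, C))
        np.add.at(gx, (bi, rows, cols, ci), g)
        return (gx,)
    out._backward = backward
    return out


def dropout(x: Tensor, rate: float, rng: np.random.Generator,
            train: bool) -> Tensor:
    """Inverted dropout: active only in training mode."""
    if not train or rate <= 0.0:
        return x
    keep = rng.random(x.data.shape) >= rate
    scale = keep / (1.0 - rate)
    out = Tensor(x.data * scale, parents=(x,))
    out._backward = lambda g: (g * scale,)
    return out


def softmax_probs(logits: np.ndarray) -> np.ndarray:
    """Row-wise stabilized softmax of a (B, K) logit array."""
    z = logits - logits.max(axis=-1, keepdims=True)
    e = np.exp(z)
    return e / e.sum(axis=-1, keepdims=True)


def softmax_cross_entropy(logits: Tensor, onehot: np.ndarray) -> Tensor:
    """Mean categorical cross-entropy with a fused softmax gradient."""
    p = softmax_probs(logits.data)
    B = logits.data.shape[0]
    eps = 1e-12
    loss = -np.sum(onehot * np.log(p + eps)) / B
    out = Tensor(loss, parents=(logits,))
    out._backward = lambda g: (g * (p - onehot) / B,)
    return out


class Adam:
    """Adam optimizer over a list of parameter Tensors."""

    def __init__(self, params: list[Tensor], lr: float = 1e-3,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1, self.beta2, self.eps = beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in params]
        self.v = [np.zeros_like(p.data) for p in params]
        self.t = 0

    def step(self, max_grad_norm: float | None = 5.0) -> None:
        self.t += 1
        grads = [p.grad if p.grad is not None else np.zeros_like(p.data)
                 for p in self.params]
        if max_grad_norm is not None:
            total = np.sqrt(sum(float((g * g).sum()) for g in grads))
            if total > max_grad_norm:
                grads = [g * (max_grad_norm / total) for g in grads]
        for p, g, m, v in zip(self.params, grads, self.m, self.v):
            m *= self.beta1
            m += (1 - self.beta1) * g
            v *= self.beta2
            v += (1 - self.beta2) * g * g
            mhat = m / (1 - self.beta1 ** self.t)
            vhat = v / (1 - self.beta2 ** self.t)
            p.data -= self.lr * mhat / (np.sqrt(vhat) + self.eps)

    def zero_grad(self) -> None:
        for p in self.params:
            p.grad = None
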