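"""Dependency-light reference implementations of the network primitives.

Ground-truth, readable versions of every operation the classifier is
built from — the LSTM cell recurrences, valid 2-D convolution
(cross-correlation orientation), max pooling, dense layers and softmax.
They exist to validate the training backend: every production layer
must agree with these references on seeded random inputs.  No
performance tricks, no gradients.

LSTM cell, with [h, x] the concatenated previous hidden state and
current input:

    f_t = sigmoid(W_f @ [h, x] + b_f)        (forget gate)
    i_t = sigmoid(W_i @ [h, x] + b_i)        (input gate)
    c~  = tanh   (W_c @ [h, x] + b_c)        (candidate state)
    C_t = f_t * C_{t-1} + i_t * c~
    o_t = sigmoid(W_o @ [h, x] + b_o)        (output gate)
    h_t = o_t * tanh(C_t)
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = [
    "LSTMParams",
    "LSTMState",
    "lstm_step",
    "lstm_sequence",
    "conv2d_valid",
    "max_pool",
    "activations",
    "dense",
    "softmax",
]


def _sigmoid(x):
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class LSTMParams:
    """Gate parameters; every W acts on the concatenation [h_{t-1}, x_t]."""

    W_f: np.ndarray
    W_i: np.ndarray
    W_c: np.ndarray
    W_o: np.ndarray
    b_f: np.ndarray
    b_i: np.ndarray
    b_c: np.ndarray
    b_o: np.ndarray

    @property
    def hidden_size(self) -> int:
        return self.W_f.shape[0]

    @property
    def input_size(self) -> int:
        return self.W_f.shape[1] - self.W_f.shape[0]

    def validate(self) -> None:
        shape = self.W_f.shape
        if shape[1] <= shape[0]:
            raise ValueError("weight matrices must act on [h, x] with x non-empty")
        for name in ("W_i", "W_c", "W_o"):
            if getattr(self, name).shape != shape:
                raise ValueError(f"{name} shape {getattr(self, name).shape} != {shape}")
        for name in ("b_f", "b_i", "b_c", "b_o"):
            if getattr(self, name).shape != (shape[0],):
                raise ValueError(f"{name} must have length hidden_size={shape[0]}")

    @classmethod
    def random(cls, hidden_size: int, input_size: int,
               seed: int = 0, scale: float = 0.5) -> "LSTMParams":
        rng = np.random.default_rng(seed)
        w = lambda: rng.uniform(-scale, scale, (hidden_size, hidden_size + input_size))
        b = lambda: rng.uniform(-scale, scale, hidden_size)
        return cls(W_f=w(), W_i=w(), W_c=w(), W_o=w(),
                   b_f=b(), b_i=b(), b_c=b(), b_o=b())


@dataclass
class LSTMState:
    h: np.ndarray
    C: np.ndarray

    @classmethod
    def zeros(cls, hidden_size: int) -> "LSTMState":
        return cls(h=np.zeros(hidden_size), C=np.zeros(hidden_size))


def lstm_step(params: LSTMParams, state: LSTMState,
              x_t: np.ndarray) -> LSTMState:
    """One LSTM cell update (see module docstring for the recurrences)."""
    params.validate()
    x_t = np.asarray(x_t, dtype=float)
    if x_t.shape != (params.input_size,):
        raise ValueError(
            f"x_t has shape {x_t.shape}, expected ({params.input_size},)")
    if state.h.shape != (params.hidden_size,):
        raise ValueError("state size does not match params")
    hx = np.concatenate([state.h, x_t])
    f_t = _sigmoid(params.W_f @ hx + params.b_f)
    i_t = _sigmoid(params.W_i @ hx + params.b_i)
    c_tilde = np.tanh(params.W_c @ hx + params.b_c)
    C_t = f_t * state.C + i_t * c_tilde
    o_t = _sigmoid(params.W_o @ hx + params.b_o)
    h_t = o_t * np.tanh(C_t)
    return LSTMState(h=h_t, C=C_t)


def lstm_sequence(params: LSTMParams, inputs, return_all: bool = False):
    """Fold :func:`lstm_step` over a sequence from the zero initial state.

    Returns the (T, hidden) array of all hidden states when
    ``return_all``, else the final hidden state.  An empty sequence
    returns the zero initial state (or an empty array).
    """
    params.validate()
    state = LSTMState.zeros(params.hidden_size)
    hs = []
    for x_t in inputs:
        x_t = np.asarray(x_t, dtype=float)
        if x_t.shape != (params.input_size,):
            raise ValueError(
                f"input of shape {x_t.shape}, expected ({params.input_size},)")
        state = lstm_step(params, state, x_t)
        hs.append(state.h)
    if return_all:
        return np.array(hs) if hs else np.zeros((0, params.hidden_size))
    return state.h


def conv2d_valid(I: np.ndarray, K: np.ndarray, b: float = 0.0) -> np.ndarray:
    """Valid 2-D convolution C[i,j] = sum_m sum_n I[i+m, j+n]*K[m,n] + b.

    Cross-correlation orientation (no kernel flip), stride 1, no
    padding; output size (H-kH+1, W-kW+1).
    """
    I = np.asarray(I, dtype=float)
    K = np.asarray(K, dtype=float)
    kh, kw = K.shape
    h, w = I.shape
    if kh > h or kw > w:
        raise ValueError(f"kernel {K.shape} larger than input {I.shape}")
    out = np.full((h - kh + 1, w - kw + 1), float(b))
    for m in range(kh):
        for n in range(kw):
            out += K[m, n] * I[m:m + out.shape[0], n:n + out.shape[1]]
    return out


@dataclass(frozen=True)
class PoolSpec:
    window: tuple = (2, 2)
    stride: int = 2

    def validate(self) -> None:
        k, l = self.window
        if k < 1 or l < 1 or self.stride < 1:
            raise ValueError("pool window and stride must be >= 1")


def max_pool(I: np.ndarray, spec: PoolSpec = PoolSpec()) -> np.ndarray:
    """Max pooling O[i,j] = max over the (k,l) window at stride s.

    Trailing windows that do not fit are dropped (no padding).
    """
    spec.validate()
    I = np.asarray(I, dtype=float)
    k, l = spec.window
    s = spec.stride
    h, w = I.shape
    if k > h or l > w:
        raise ValueError(f"pool window {spec.window} exceeds input {I.shape}")
    oh = (h - k) // s + 1
    ow = (w - l) // s + 1
    out = np.empty((oh, ow))
    for i in range(oh):
        for j in range(ow):
            out[i, j] = I[i * s:i * s + k, j * s:j * s + l].max()
    return out


def activations(x, kind: str):
    """Elementwise activation: relu f(x)=max(0,x), sigmoid or tanh."""
    x = np.asarray(x, dtype=float)
    if kind == "relu":
        return np.maximum(0.0, x)
    if kind == "sigmoid":
        return _sigmoid(x)
    if kind == "tanh":
        return np.tanh(x)
    raise ValueError(f"unknown activation {kind!r}")


@dataclass
class DenseSoftmaxParams:
    W: np.ndarray
    b: np.ndarray
    activation: str = "relu"


def dense(x: np.ndarray, params: DenseSoftmaxParams) -> np.ndarray:
    """Fully connected layer z = f(W @ x + b)."""
    x = np.asarray(x, dtype=float)
    if params.W.shape[1] != x.shape[0] or params.W.shape[0] != params.b.shape[0]:
        raise ValueError(
            f"shape mismatch: W {params.W.shape}, b {params.b.shape}, x {x.shape}")
    z = params.W @ x + params.b
    if params.activation in (None, "identity", "linear"):
        return z
    return activations(z, params.activation)


def softmax(z: np.ndarray) -> np.ndarray:
    """P(y=j) = exp(z_j) / sum_k exp(z_k), stabilized by max-subtraction."""
    z = np.asarray(z, dtype=float)
    if z.size == 0:
        raise ValueError("softmax of an empty vector")
    if not np.all(np.isfinite(z)):
        raise ValueError("softmax input must be finite")
    e = np.exp(z - z.max())
    return e / e.sum()
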