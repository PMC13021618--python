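"""Minimal numpy neural-network engine for the sequence forecasters.

A small reverse-mode autodiff over ``numpy`` arrays plus the three sequence
architectures used for feeding-intensity forecasting (stacked LSTM, stacked
GRU, single-head Transformer encoder) and an Adam optimizer with early
stopping.  Everything is seeded and runs in float32 on the CPU.
"""

from __future__ import annotations

import math
from typing import Callable, Sequence

import numpy as np

DTYPE = np.float32

__all__ = [
    "Tensor",
    "Adam",
    "LSTMNet",
    "GRUNet",
    "TransformerNet",
    "build_net",
]


def _unbroadcast(grad: np.ndarray, shape: tuple[int, ...]) -> np.ndarray:
    """Sum a gradient down to the shape of the broadcast operand."""
    if grad.shape == shape:
        return grad
    extra = grad.ndim - len(shape)
    if extra > 0:
        grad = grad.sum(axis=tuple(range(extra)))
    axes = tuple(i for i, n in enumerate(shape) if n == 1 and grad.shape[i] != 1)
    if axes:
        grad = grad.sum(axis=axes, keepdims=True)
    return grad.reshape(shape)


class Tensor:
    """Array node in the autodiff graph."""

    __slots__ = ("data", "grad", "_parents", "_backward", "requires_grad")

    def __init__(self, data, parents=(), backward=None, requires_grad=False):
        self.data = np.asarray(data, dtype=DTYPE)
        self.grad: np.ndarray | None = None
        self._parents: tuple[Tensor, ...] = parents
        self._backward: Callable[[np.ndarray], None] | None = backward
        self.requires_grad = requires_grad or any(p.requires_grad for p in parents)

    @property
    def shape(self):
        return self.data.shape

    # -- graph construction helpers -------------------------------------
    @staticmethod
    def _lift(other) -> "Tensor":
        return other if isinstance(other, Tensor) else Tensor(other)

    def _make(self, data, parents, backward):
        out = Tensor(data, parents=parents, backward=backward)
        return out

    # -- arithmetic ------------------------------------------------------
    def __add__(self, other):
        other = self._lift(other)
        out_data = self.data + other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __radd__ = __add__

    def __sub__(self, other):
        other = self._lift(other)
        out_data = self.data - other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(-g, other.data.shape))

        return self._make(out_data, (self, other), backward)

    def __rsub__(self, other):
        return self._lift(other) - self

    def __mul__(self, other):
        other = self._lift(other)
        out_data = self.data * other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g * other.data, self.data.shape))
            if other.requires_grad:
                other._accum(_unbroadcast(g * self.data, other.data.shape))

        return self._make(out_data, (self, other), backward)

    __rmul__ = __mul__

    def __truediv__(self, other):
        other = self._lift(other)
        out_data = self.data / other.data

        def backward(g):
            if self.requires_grad:
                self._accum(_unbroadcast(g / other.data, self.data.shape))
            if other.requires_grad:
                other._accum(
                    _unbroadcast(-g * self.data / other.data**2, other.data.shape)
                )

        return self._make(out_data, (self, other), backward)

    def __neg__(self):
        return self * -1.0

    def __matmul__(self, other):
        other = self._lift(other)
        out_data = self.data @ other.data

        def backward(g):
            if self.requires_grad:
                ga = g @ np.swapaxes(other.data, -1, -2)
                self._accum(_unbroadcast(ga, self.data.shape))
            if other.requires_grad:
                gb = np.swapaxes(self.data, -1, -2) @ g
                other._accum(_unbroadcast(gb, other.data.shape))

        return self._make(out_data, (self, other), backward)

    def __getitem__(self, idx):
        # basic (slice) indexing only; grads are written into a shared buffer
        out_data = self.data[idx]

        def backward(g):
            if self.requires_grad:
                if self.grad is None:
                    self.grad = np.zeros_like(self.data)
                self.grad[idx] += g

        return self._make(out_data, (self,), backward)

    # -- reductions / shaping -------------------------------------------
    def sum(self, axis=None, keepdims=False):
        out_data = self.data.sum(axis=axis, keepdims=keepdims)

        def backward(g):
            if not self.requires_grad:
                return
            if axis is None:
                grad = np.broadcast_to(g, self.data.shape)
            else:
                gg = g if keepdims else np.expand_dims(g, axis)
                grad = np.broadcast_to(gg, self.data.shape)
            self._accum(grad.astype(DTYPE, copy=True))

        return self._make(out_data, (self,), backward)

    def mean(self, axis=None, keepdims=False):
        n = self.data.size if axis is None else self.data.shape[axis]
        return self.sum(axis=axis, keepdims=keepdims) * (1.0 / n)

    def reshape(self, *shape):
        old = self.data.shape
        out_data = self.data.reshape(*shape)

        def backward(g):
            if self.requires_grad:
                self._accum(g.reshape(old))

        return self._make(out_data, (self,), backward)

    def swap_last(self):
        """Transpose the last two axes."""
        out_data = np.swapaxes(self.data, -1, -2)

        def backward(g):
            if self.requires_grad:
                self._accum(np.swapaxes(g, -1, -2))

        return self._make(out_data, (self,), backward)

    # -- nonlinearities --------------------------------------------------
    def tanh(self):
        out_data = np.tanh(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (1.0 - out_data**2))

        return self._make(out_data, (self,), backward)

    def sigmoid(self):
        out_data = 1.0 / (1.0 + np.exp(-self.data))

        def backward(g):
            if self.requires_grad:
                self._accum(g * out_data * (1.0 - out_data))

        return self._make(out_data, (self,), backward)

    def relu(self):
        out_data = np.maximum(self.data, 0.0)

        def backward(g):
            if self.requires_grad:
                self._accum(g * (self.data > 0))

        return self._make(out_data, (self,), backward)

    def sqrt(self):
        out_data = np.sqrt(self.data)

        def backward(g):
            if self.requires_grad:
                self._accum(g * 0.5 / out_data)

        return self._make(out_data, (self,), backward)

    def softmax_last(self):
        """Softmax over the last axis (attention weights)."""
        shifted = self.data - self.data.max(axis=-1, keepdims=True)
        e = np.exp(shifted)
        out_data = e / e.sum(axis=-1, keepdims=True)

        def backward(g):
            if self.requires_grad:
                dot = (g * out_data).sum(axis=-1, keepdims=True)
                self._accum(out_data * (g - dot))

        return self._make(out_data, (self,), backward)

    def dropout(self, rate: float, rng: np.random.Generator | None):
        """Inverted dropout; identity when rate is 0 or no rng (eval mode)."""
        if rate <= 0 or rng is None:
            return self
        mask = (rng.random(self.data.shape) >= rate) / (1.0 - rate)
        return self * Tensor(mask.astype(DTYPE))

    # -- backprop ---------------------------------------------------------
    def _accum(self, g: np.ndarray) -> None:
        if self.grad is None:
            self.grad = g.astype(DTYPE, copy=True)
        else:
            self.grad += g

    def backward(self) -> None:
        order: list[Tensor] = []
        seen: set[int] = set()
        stack: list[tuple[Tensor, bool]] = [(self, False)]
        while stack:
            node, processed = stack.pop()
            if processed:
                order.append(node)
                continue
            if id(node) in seen or not node.requires_grad:
                continue
            seen.add(id(node))
            stack.append((node, True))
            for p in node._parents:
                stack.append((p, False))
        self.grad = np.ones_like(self.data)
        for node in reversed(order):
            if node._backward is not None and node.grad is not None:
                node._backward(node.grad)


def parameter(rng: np.random.Generator, *shape, scale: float | None = None) -> Tensor:
    """Glorot-uniform weight tensor marked as trainable."""
    if scale is None:
        fan_in = shape[0] if len(shape) > 1 else shape[0]
        fan_out = shape[-1]
        scale = math.sqrt(6.0 / (fan_in + fan_out))
    t = Tensor(rng.uniform(-scale, scale, shape))
    t.requires_grad = True
    return t


def zeros_param(*shape) -> Tensor:
    t = Tensor(np.zeros(shape))
    t.requires_grad = True
    return t


class Dense:
    def __init__(self, rng, n_in, n_out):
        self.w = parameter(rng, n_in, n_out)
        self.b = zeros_param(n_out)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.w + self.b

    def parameters(self):
        return [self.w, self.b]


class LSTMLayer:
    """Single LSTM layer with tanh cell activation (gate order i, f, g, o)."""

    def __init__(self, rng, n_in, hidden):
        self.hidden = hidden
        self.w_x = parameter(rng, n_in, 4 * hidden)
        self.w_h = parameter(rng, hidden, 4 * hidden)
        b = np.zeros(4 * hidden, dtype=DTYPE)
        b[hidden : 2 * hidden] = 1.0  # forget-gate bias
        self.b = Tensor(b)
        self.b.requires_grad = True

    def parameters(self):
        return [self.w_x, self.w_h, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        """x: (B, T, n_in) -> stacked hidden states (B, T, hidden)."""
        bsz, tlen, n_in = x.shape
        h = self.hidden
        xw = x.reshape(bsz * tlen, n_in) @ self.w_x + self.b
        xw = xw.reshape(bsz, tlen, 4 * h)
        h_t = Tensor(np.zeros((bsz, h)))
        c_t = Tensor(np.zeros((bsz, h)))
        outs = []
        for t in range(tlen):
            gates = xw[:, t, :] + h_t @ self.w_h
            i_g = gates[:, 0:h].sigmoid()
            f_g = gates[:, h : 2 * h].sigmoid()
            g_g = gates[:, 2 * h : 3 * h].tanh()
            o_g = gates[:, 3 * h : 4 * h].sigmoid()
            c_t = f_g * c_t + i_g * g_g
            h_t = o_g * c_t.tanh()
            outs.append(h_t)
        return _stack_time(outs)


class GRULayer:
    """Single GRU layer (gate order z, r, n)."""

    def __init__(self, rng, n_in, hidden):
        self.hidden = hidden
        self.w_x = parameter(rng, n_in, 3 * hidden)
        self.w_h = parameter(rng, hidden, 3 * hidden)
        self.b = zeros_param(3 * hidden)

    def parameters(self):
        return [self.w_x, self.w_h, self.b]

    def __call__(self, x: Tensor) -> Tensor:
        bsz, tlen, n_in = x.shape
        h = self.hidden
        xw = x.reshape(bsz * tlen, n_in) @ self.w_x + self.b
        xw = xw.reshape(bsz, tlen, 3 * h)
        h_t = Tensor(np.zeros((bsz, h)))
        outs = []
        for t in range(tlen):
            hw = h_t @ self.w_h
            z_g = (xw[:, t, 0:h] + hw[:, 0:h]).sigmoid()
            r_g = (xw[:, t, h : 2 * h] + hw[:, h : 2 * h]).sigmoid()
            n_g = (xw[:, t, 2 * h : 3 * h] + r_g * hw[:, 2 * h : 3 * h]).tanh()
            h_t = (1.0 - z_g) * n_g + z_g * h_t
            outs.append(h_t)
        return _stack_time(outs)


def _stack_time(states: Sequence[Tensor]) -> Tensor:
    """Stack per-step (B, H) states into (B, T, H)."""
    datas = np.stack([s.data for s in states], axis=1)

    def backward(g):
        for t, s in enumerate(states):
            if s.requires_grad:
                s._accum(g[:, t, :])

    return Tensor(datas, parents=tuple(states), backward=backward)


class LayerNorm:
    def __init__(self, dim, eps=1e-5):
        self.gamma = zeros_param(dim)
        self.gamma.data += 1.0
        self.beta = zeros_param(dim)
        self.eps = eps

    def parameters(self):
        return [self.gamma, self.beta]

    def __call__(self, x: Tensor) -> Tensor:
        mu = x.mean(axis=-1, keepdims=True)
        xc = x - mu
        var = (xc * xc).mean(axis=-1, keepdims=True)
        return xc / (var + self.eps).sqrt() * self.gamma + self.beta


class LSTMNet:
    """Two stacked LSTM layers (tanh), dropout, dense-64 ReLU, linear head."""

    arch = "lstm"

    def __init__(self, rng, n_features, hidden=128, n_layers=2, dropout=0.2,
                 dense=64, output_dim=1):
        self.dropout_rate = dropout
        self.layers = []
        n_in = n_features
        for _ in range(n_layers):
            self.layers.append(LSTMLayer(rng, n_in, hidden))
            n_in = hidden
        self.dense = Dense(rng, hidden, dense)
        self.head = Dense(rng, dense, output_dim)
        self.output_dim = output_dim

    def parameters(self):
        ps = []
        for layer in self.layers:
            ps += layer.parameters()
        return ps + self.dense.parameters() + self.head.parameters()

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        for layer in self.layers:
            x = layer(x)
        last = x[:, -1, :]
        last = last.dropout(self.dropout_rate, rng)
        return self.head(self.dense(last).relu())


class GRUNet(LSTMNet):
    arch = "gru"

    def __init__(self, rng, n_features, hidden=128, n_layers=2, dropout=0.2,
                 dense=64, output_dim=1):
        self.dropout_rate = dropout
        self.layers = []
        n_in = n_features
        for _ in range(n_layers):
            self.layers.append(GRULayer(rng, n_in, hidden))
            n_in = hidden
        self.dense = Dense(rng, hidden, dense)
        self.head = Dense(rng, dense, output_dim)
        self.output_dim = output_dim


class TransformerNet:
    """Two-block single-head Transformer encoder with positional encoding."""

    arch = "transformer"

    def __init__(self, rng, n_features, context_len=50, d_model=128, d_ff=256,
                 n_blocks=2, dropout=0.2, output_dim=1):
        self.dropout_rate = dropout
        self.embed = Dense(rng, n_features, d_model)
        self.pos = Tensor(_positional_encoding(context_len, d_model))
        self.d_model = d_model
        self.blocks = []
        for _ in range(n_blocks):
            blk = {
                "wq": Dense(rng, d_model, d_model),
                "wk": Dense(rng, d_model, d_model),
                "wv": Dense(rng, d_model, d_model),
                "wo": Dense(rng, d_model, d_model),
                "ln1": LayerNorm(d_model),
                "ff1": Dense(rng, d_model, d_ff),
                "ff2": Dense(rng, d_ff, d_model),
                "ln2": LayerNorm(d_model),
            }
            self.blocks.append(blk)
        self.head = Dense(rng, d_model, output_dim)
        self.output_dim = output_dim

    def parameters(self):
        ps = self.embed.parameters() + self.head.parameters()
        for blk in self.blocks:
            for key in ("wq", "wk", "wv", "wo", "ln1", "ff1", "ff2", "ln2"):
                ps += blk[key].parameters()
        return ps

    def forward(self, x: Tensor, rng: np.random.Generator | None = None) -> Tensor:
        h = self.embed(x) + self.pos
        scale = 1.0 / math.sqrt(self.d_model)
        for blk in self.blocks:
            q, k, v = blk["wq"](h), blk["wk"](h), blk["wv"](h)
            scores = (q @ k.swap_last()) * scale
            attn = scores.softmax_last() @ v
            h = blk["ln1"](h + blk["wo"](attn).dropout(self.dropout_rate, rng))
            ff = blk["ff2"](blk["ff1"](h).relu())
            h = blk["ln2"](h + ff.dropout(self.dropout_rate, rng))
        return self.head(h[:, -1, :])


def _positional_encoding(length: int, dim: int) -> np.ndarray:
    pos = np.arange(length)[:, None]
    i = np.arange(dim // 2)[None, :]
    angle = pos / np.power(10000.0, 2 * i / dim)
    pe = np.zeros((length, dim), dtype=DTYPE)
    pe[:, 0::2] = np.sin(angle)
    pe[:, 1::2] = np.cos(angle)
    return pe


def build_net(arch: str, rng: np.random.Generator, n_features: int,
              context_len: int, output_dim: int, hidden: int = 128,
              dropout: float = 0.2, dense: int = 64, d_ff: int = 256,
              n_layers: int = 2) -> LSTMNet | GRUNet | TransformerNet:
    if arch == "lstm":
        return LSTMNet(rng, n_features, hidden, n_layers, dropout, dense, output_dim)
    if arch == "gru":
        return GRUNet(rng, n_features, hidden, n_layers, dropout, dense, output_dim)
    if arch == "transformer":
        return TransformerNet(rng, n_features, context_len, hidden, d_ff,
                              n_layers, dropout, output_dim)
    raise ValueError(f"unknown architecture {arch!r}")


class Adam:
    def __init__(self, params: Sequence[Tensor], lr=1e-3, beta1=0.9, beta2=0.999,
                 eps=1e-8):
        self.params = list(params)
        self.lr, self.b1, self.b2, self.eps = lr, beta1, beta2, eps
        self.m = [np.zeros_like(p.data) for p in self.params]
        self.v = [np.zeros_like(p.data) for p in self.params]
        self.t = 0

    def zero_grad(self):
        for p in self.params:
            p.grad = None

    def step(self):
        self.t += 1
        b1t = 1.0 - self.b1**self.t
        b2t = 1.0 - self.b2**self.t
        for i, p in enumerate(self.params):
            if p.grad is None:
                continue
            g = p.grad
            self.m[i] = self.b1 * self.m[i] + (1 - self.b1) * g
            self.v[i] = self.b2 * self.v[i] + (1 - self.b2) * g * g
            p.data -= self.lr * (self.m[i] / b1t) / (np.sqrt(self.v[i] / b2t) + self.eps)

    def state_snapshot(self) -> list[np.ndarray]:
        return [p.data.copy() for p in self.params]

    def restore(self, snapshot: list[np.ndarray]) -> None:
        for p, d in zip(self.params, snapshot):
            p.data = d.copy()
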