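"""Neural-network layers for 1-D biosignal models.

Conventions
-----------
* Convolutional feature maps are ``(batch, channels, time)``.
* Recurrent layers take ``(batch, time, features)``.
* All convolutions use TensorFlow-style "same" padding with ceiling length
  division, so a stride-``s`` conv maps length ``T`` to ``ceil(T/s)`` and
  time lengths stay predictable for any input length.
* Weights are variance-scaling initialised, recurrent kernels orthogonal,
  biases zero; every ``Module`` draws from the ``numpy.random.Generator``
  handed to its constructor, so builds are reproducible from one seed.
"""

from __future__ import annotations

import math

import numpy as np

from .autograd import Tensor, concatenate, stack


class Module:
    """Minimal parameter container with named-parameter traversal."""

    def _children(self):
        for name, val in vars(self).items():
            if isinstance(val, Module):
                yield name, val
            elif isinstance(val, (list, tuple)):
                for i, v in enumerate(val):
                    if isinstance(v, Module):
                        yield f"{name}.{i}", v

    def named_parameters(self, prefix: str = ""):
        for name, val in vars(self).items():
            if isinstance(val, Tensor) and val.requires_grad:
                yield prefix + name, val
        for cname, child in self._children():
            yield from child.named_parameters(prefix + cname + ".")

    def parameters(self):
        seen, out = set(), []
        for _, p in self.named_parameters():
            if id(p) not in seen:
                seen.add(id(p))
                out.append(p)
        return out

    def n_parameters(self) -> int:
        return sum(p.size for p in self.parameters())

    def state_dict(self) -> dict:
        return {name: p.data.copy() for name, p in self.named_parameters()}

    def load_state_dict(self, state: dict):
        own = dict(self.named_parameters())
        missing = set(own) - set(state)
        if missing:
            raise KeyError(f"checkpoint missing parameters: {sorted(missing)[:3]}")
        for name, p in own.items():
            if state[name].shape != p.data.shape:
                raise ValueError(
                    f"checkpoint/config mismatch at {name!r}: "
                    f"{state[name].shape} vs {p.data.shape}"
                )
            p.data[...] = state[name]


def _variance_scaling(rng: np.random.Generator, shape, fan_in: int) -> np.ndarray:
    return rng.normal(0.0, math.sqrt(2.0 / fan_in), size=shape)


def _orthogonal(rng: np.random.Generator, rows: int, cols: int) -> np.ndarray:
    a = rng.normal(size=(max(rows, cols), min(rows, cols)))
    q, r = np.linalg.qr(a)
    q = q * np.sign(np.diag(r))
    return q[:rows, :cols] if rows >= cols else q.T[:rows, :cols]


def same_pad_amount(length: int, kernel: int, stride: int, dilation: int = 1):
    """Left/right zero-padding for out_len = ceil(length/stride)."""
    eff = (kernel - 1) * dilation + 1
    out_len = -(-length // stride)
    total = max((out_len - 1) * stride + eff - length, 0)
    return total // 2, total - total // 2


class Conv1d(Module):
    """1-D convolution with stride and dilation, 'same' zero padding."""

    def __init__(self, in_channels, out_channels, kernel, stride=1,
                 dilation=1, rng: np.random.Generator | None = None):
        rng = rng or np.random.default_rng()
        self.in_channels = in_channels
        self.out_channels = out_channels
        self.kernel = kernel
        self.stride = stride
        self.dilation = dilation
        fan_in = in_channels * kernel
        self.weight = Tensor(
            _variance_scaling(rng, (out_channels, in_channels, kernel), fan_in),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_channels), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        _, c, t = x.shape
        if c != self.in_channels:
            raise ValueError(f"expected {self.in_channels} channels, got {c}")
        left, right = same_pad_amount(t, self.kernel, self.stride, self.dilation)
        xp = x.pad_axis(2, left, right)
        out_len = -(-t // self.stride)
        # (out_len, kernel) index grid into the padded time axis
        starts = np.arange(out_len) * self.stride
        taps = np.arange(self.kernel) * self.dilation
        idx = starts[:, None] + taps[None, :]
        # gather -> (B, C, out_len, K) -> (B, out_len, C*K)
        cols = xp.take_axis(idx, axis=2)
        cols = cols.transpose(0, 2, 1, 3).reshape(-1, out_len, c * self.kernel)
        w = self.weight.reshape(self.out_channels, c * self.kernel)
        out = cols @ w.transpose(1, 0) + self.bias
        return out.transpose(0, 2, 1)  # (B, out_channels, out_len)


class Dense(Module):
    """Affine map on the last axis."""

    def __init__(self, in_features, out_features, rng=None):
        rng = rng or np.random.default_rng()
        self.weight = Tensor(
            _variance_scaling(rng, (in_features, out_features), in_features),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(out_features), requires_grad=True)

    def __call__(self, x: Tensor) -> Tensor:
        return x @ self.weight + self.bias


def max_pool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping max pool over time, ceil mode (pads with -inf)."""
    b, c, t = x.shape
    out_len = -(-t // pool)
    pad = out_len * pool - t
    if pad:
        x = x.pad_axis(2, 0, pad, value=-np.inf)
    return x.reshape(b, c, out_len, pool).max(axis=3)


def avg_pool1d(x: Tensor, pool: int) -> Tensor:
    """Non-overlapping average pool, ceil mode (partial window averaged
    over its true sample count)."""
    b, c, t = x.shape
    out_len = -(-t // pool)
    pad = out_len * pool - t
    if pad:
        x = x.pad_axis(2, 0, pad, value=0.0)
    counts = np.full(out_len, pool, dtype=float)
    if pad:
        counts[-1] = pool - pad
    s = x.reshape(b, c, out_len, pool).sum(axis=3)
    return s * Tensor(1.0 / counts)


def global_avg_pool(x: Tensor) -> Tensor:
    """(B, C, T) -> (B, C): mean over the whole time axis."""
    return x.mean(axis=2)


class Dropout(Module):
    """Inverted dropout parameterised by *keep* probability."""

    def __init__(self, keep: float = 0.5):
        if not 0.0 < keep <= 1.0:
            raise ValueError("dropout keep rate must lie in (0, 1]")
        self.keep = keep

    def __call__(self, x: Tensor, train: bool, rng: np.random.Generator | None):
        if not train or self.keep >= 1.0:
            return x
        mask = (rng.random(x.shape) < self.keep) / self.keep
        return x * Tensor(mask)


class _RecurrentCellBase(Module):
    def __init__(self, in_features, hidden, n_gates, rng):
        self.hidden = hidden
        self.w_x = Tensor(
            _variance_scaling(rng, (in_features, n_gates * hidden), in_features),
            requires_grad=True,
        )
        self.w_h = Tensor(
            np.concatenate(
                [_orthogonal(rng, hidden, hidden) for _ in range(n_gates)], axis=1
            ),
            requires_grad=True,
        )
        self.bias = Tensor(np.zeros(n_gates * hidden), requires_grad=True)


class GRUCell(_RecurrentCellBase):
    """Gated recurrent unit (reset/update gates, candidate state)."""

    def __init__(self, in_features, hidden, rng=None):
        super().__init__(in_features, hidden, 3, rng or np.random.default_rng())

    def step(self, x: Tensor, h: Tensor) -> Tensor:
        n = self.hidden
        gx = x @ self.w_x + self.bias
        gh = h @ self.w_h
        r = (gx[:, :n] + gh[:, :n]).sigmoid()
        z = (gx[:, n:2 * n] + gh[:, n:2 * n]).sigmoid()
        cand = (gx[:, 2 * n:] + r * gh[:, 2 * n:]).tanh()
        return z * h + (1.0 - z) * cand


class LSTMCell(_RecurrentCellBase):
    """LSTM with input/forget/cell/output gates."""

    def __init__(self, in_features, hidden, rng=None):
        super().__init__(in_features, hidden, 4, rng or np.random.default_rng())

    def step(self, x: Tensor, h: Tensor, c: Tensor):
        n = self.hidden
        g = x @ self.w_x + h @ self.w_h + self.bias
        i = g[:, :n].sigmoid()
        f = g[:, n:2 * n].sigmoid()
        cand = g[:, 2 * n:3 * n].tanh()
        o = g[:, 3 * n:].sigmoid()
        c_new = f * c + i * cand
        return o * c_new.tanh(), c_new


def _run_direction(cell, x: Tensor, reverse: bool):
    """Run a recurrent cell over (B, T, F); returns per-step outputs and
    the final hidden state of that direction."""
    b, t, _ = x.shape
    h = Tensor(np.zeros((b, cell.hidden)))
    c = Tensor(np.zeros((b, cell.hidden))) if isinstance(cell, LSTMCell) else None
    order = range(t - 1, -1, -1) if reverse else range(t)
    outs = [None] * t
    for i in order:
        xi = x[:, i, :]
        if c is None:
            h = cell.step(xi, h)
        else:
            h, c = cell.step(xi, h, c)
        outs[i] = h
    return stack(outs, axis=1), h


class BiGRU(Module):
    """Bidirectional GRU; ``last_states`` concatenates the final step of
    the forward pass with the final step of the backward pass."""

    def __init__(self, in_features, hidden, rng=None):
        rng = rng or np.random.default_rng()
        self.fwd = GRUCell(in_features, hidden, rng)
        self.bwd = GRUCell(in_features, hidden, rng)

    def __call__(self, x: Tensor):
        out_f, last_f = _run_direction(self.fwd, x, reverse=False)
        out_b, last_b = _run_direction(self.bwd, x, reverse=True)
        return concatenate([out_f, out_b], axis=2), concatenate(
            [last_f, last_b], axis=1
        )


class BiLSTM(Module):
    """Bidirectional LSTM returning per-step concatenated outputs."""

    def __init__(self, in_features, hidden, rng=None):
        rng = rng or np.random.default_rng()
        self.fwd = LSTMCell(in_features, hidden, rng)
        self.bwd = LSTMCell(in_features, hidden, rng)

    def __call__(self, x: Tensor) -> Tensor:
        out_f, _ = _run_direction(self.fwd, x, reverse=False)
        out_b, _ = _run_direction(self.bwd, x, reverse=True)
        return concatenate([out_f, out_b], axis=2)
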