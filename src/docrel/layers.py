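"""NumPy neural-network primitives with handwritten backward passes.

Everything here is deliberately self-contained: a gated LSTM cell (input,
forget, cell and output gates with sigmoid/tanh nonlinearities), masked
time-major sequence application in either direction, a bidirectional
wrapper, affine layers, inverted dropout, softmax cross-entropy and Adam.

Shapes are time-major: sequences are ``[T, B, D]`` with a ``[T, B]``
validity mask (1 = real token, 0 = padding; padding is always a suffix).
At padded positions the recurrent state is carried through unchanged, so
padding a batch never changes per-sequence results.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np


def sigmoid(x: np.ndarray) -> np.ndarray:
    out = np.empty_like(x)
    pos = x >= 0
    out[pos] = 1.0 / (1.0 + np.exp(-x[pos]))
    ex = np.exp(x[~pos])
    out[~pos] = ex / (1.0 + ex)
    return out


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    m = np.max(x, axis=axis, keepdims=True)
    e = np.exp(x - m)
    return e / np.sum(e, axis=axis, keepdims=True)


# ---------------------------------------------------------------------------
# LSTM cell
# ---------------------------------------------------------------------------

class LSTMParams:
    """Weights of one directional LSTM layer.

    Stored packed as ``Wx [4H, D]``, ``Wh [4H, H]``, ``bx [4H]``, ``bh [4H]``
    with gate row order (input, forget, cell, output).  The per-gate views
    (``W_ii``, ``W_hi``, ``b_ii``, ... ) expose the conventional names.
    """

    def __init__(self, input_dim: int, hidden: int,
                 rng: np.random.Generator | None = None):
        self.input_dim = input_dim
        self.hidden = hidden
        k = 1.0 / np.sqrt(hidden)
        if rng is None:
            self.Wx = np.zeros((4 * hidden, input_dim))
            self.Wh = np.zeros((4 * hidden, hidden))
        else:
            self.Wx = rng.uniform(-k, k, (4 * hidden, input_dim))
            self.Wh = rng.uniform(-k, k, (4 * hidden, hidden))
        self.bx = np.zeros(4 * hidden)
        self.bh = np.zeros(4 * hidden)

    def _rows(self, gate: int) -> slice:
        h = self.hidden
        return slice(gate * h, (gate + 1) * h)

    # conventional per-gate views (read/write, shared memory)
    @property
    def W_ii(self): return self.Wx[self._rows(0)]
    @property
    def W_if(self): return self.Wx[self._rows(1)]
    @property
    def W_ig(self): return self.Wx[self._rows(2)]
    @property
    def W_io(self): return self.Wx[self._rows(3)]
    @property
    def W_hi(self): return self.Wh[self._rows(0)]
    @property
    def W_hf(self): return self.Wh[self._rows(1)]
    @property
    def W_hg(self): return self.Wh[self._rows(2)]
    @property
    def W_ho(self): return self.Wh[self._rows(3)]
    @property
    def b_ii(self): return self.bx[self._rows(0)]
    @property
    def b_if(self): return self.bx[self._rows(1)]
    @property
    def b_ig(self): return self.bx[self._rows(2)]
    @property
    def b_io(self): return self.bx[self._rows(3)]
    @property
    def b_hi(self): return self.bh[self._rows(0)]
    @property
    def b_hf(self): return self.bh[self._rows(1)]
    @property
    def b_hg(self): return self.bh[self._rows(2)]
    @property
    def b_ho(self): return self.bh[self._rows(3)]

    def arrays(self) -> dict[str, np.ndarray]:
        return {"Wx": self.Wx, "Wh": self.Wh, "bx": self.bx, "bh": self.bh}


def lstm_step(x, h_prev, c_prev, params: LSTMParams):
    """One LSTM step.

    Gates: i = sigma(W_ii x + b_ii + W_hi h + b_hi), f and o likewise with
    their weights, g = tanh(W_ig x + b_ig + W_hg h + b_hg); then
    c = f*c_prev + i*g and h = o*tanh(c), all elementwise.

    ``x`` may be ``[D]`` or ``[B, D]``; states match.
    """
    a = x @ params.Wx.T + params.bx + h_prev @ params.Wh.T + params.bh
    h = params.hidden
    i = sigmoid(a[..., 0 * h:1 * h])
    f = sigmoid(a[..., 1 * h:2 * h])
    g = np.tanh(a[..., 2 * h:3 * h])
    o = sigmoid(a[..., 3 * h:4 * h])
    c = f * c_prev + i * g
    return o * np.tanh(c), c


@dataclass
class _LSTMCache:
    x: np.ndarray
    mask: np.ndarray
    order: list[int]
    h_prev: list[np.ndarray]
    c_prev: list[np.ndarray]
    gates: list[tuple]
    params: LSTMParams


def lstm_forward(x: np.ndarray, mask: np.ndarray, params: LSTMParams,
                 reverse: bool = False):
    """Run an LSTM over a masked time-major batch.

    Returns ``(out [T, B, H], cache)``; ``out[t]`` is the hidden state after
    consuming position ``t`` (in the given direction).  Masked positions
    carry state through unchanged.
    """
    T, B, _ = x.shape
    H = params.hidden
    gx = x @ params.Wx.T + params.bx  # [T, B, 4H], one big matmul
    h = np.zeros((B, H))
    c = np.zeros((B, H))
    out = np.zeros((T, B, H))
    order = list(range(T - 1, -1, -1)) if reverse else list(range(T))
    cache = _LSTMCache(x=x, mask=mask, order=order, h_prev=[], c_prev=[],
                       gates=[], params=params)
    for t in order:
        a = gx[t] + h @ params.Wh.T + params.bh
        i = sigmoid(a[:, 0 * H:1 * H])
        f = sigmoid(a[:, 1 * H:2 * H])
        g = np.tanh(a[:, 2 * H:3 * H])
        o = sigmoid(a[:, 3 * H:4 * H])
        c_new = f * c + i * g
        tc = np.tanh(c_new)
        h_new = o * tc
        m = mask[t][:, None]
        cache.h_prev.append(h)
        cache.c_prev.append(c)
        cache.gates.append((i, f, g, o, tc))
        h = m * h_new + (1.0 - m) * h
        c = m * c_new + (1.0 - m) * c
        out[t] = h
    return out, cache


def lstm_backward(d_out: np.ndarray, cache: _LSTMCache):
    """Backprop through :func:`lstm_forward`.

    ``d_out`` is the gradient w.r.t. the full output tensor.  Returns
    ``(d_x, grads)`` with ``grads`` keyed like ``LSTMParams.arrays()``.
    """
    p = cache.params
    T, B, _ = cache.x.shape
    H = p.hidden
    d_x = np.zeros_like(cache.x)
    dWx = np.zeros_like(p.Wx)
    dWh = np.zeros_like(p.Wh)
    dbx = np.zeros_like(p.bx)
    dbh = np.zeros_like(p.bh)
    dh = np.zeros((B, H))
    dc = np.zeros((B, H))
    for step in range(len(cache.order) - 1, -1, -1):
        t = cache.order[step]
        i, f, g, o, tc = cache.gates[step]
        h_prev = cache.h_prev[step]
        c_prev = cache.c_prev[step]
        m = cache.mask[t][:, None]
        dh = dh + d_out[t]
        dh_new = dh * m
        dh_prev = dh * (1.0 - m)
        dc_new = dc * m
        dc_prev = dc * (1.0 - m)
        do = dh_new * tc
        dc_new = dc_new + dh_new * o * (1.0 - tc * tc)
        di = dc_new * g
        df = dc_new * c_prev
        dg = dc_new * i
        dc_prev = dc_prev + dc_new * f
        da = np.concatenate([di * i * (1.0 - i), df * f * (1.0 - f),
                             dg * (1.0 - g * g), do * o * (1.0 - o)], axis=1)
        dWx += da.T @ cache.x[t]
        dWh += da.T @ h_prev
        dbx += da.sum(axis=0)
        dbh += da.sum(axis=0)
        d_x[t] = da @ p.Wx
        dh = dh_prev + da @ p.Wh
        dc = dc_prev
    return d_x, {"Wx": dWx, "Wh": dWh, "bx": dbx, "bh": dbh}


def bilstm_forward(x, mask, fwd: LSTMParams, bwd: LSTMParams):
    """Bidirectional LSTM: concatenated [forward ; backward] states.

    Returns ``(out [T, B, 2H], (cache_f, cache_b))``.
    """
    hf, cf = lstm_forward(x, mask, fwd, reverse=False)
    hb, cb = lstm_forward(x, mask, bwd, reverse=True)
    return np.concatenate([hf, hb], axis=2), (cf, cb)


def bilstm_backward(d_out, caches):
    cf, cb = caches
    H = cf.params.hidden
    dxf, gf = lstm_backward(d_out[:, :, :H], cf)
    dxb, gb = lstm_backward(d_out[:, :, H:], cb)
    return dxf + dxb, gf, gb


# ---------------------------------------------------------------------------
# Dense layers, dropout, losses
# ---------------------------------------------------------------------------

def affine_forward(x, W, b):
    """y = x @ W.T + b on the last axis; returns (y, x)."""
    return x @ W.T + b, x


def affine_backward(d_y, x, W):
    flat_dy = d_y.reshape(-1, d_y.shape[-1])
    flat_x = x.reshape(-1, x.shape[-1])
    dW = flat_dy.T @ flat_x
    db = flat_dy.sum(axis=0)
    dx = d_y @ W
    return dx.reshape(x.shape), dW, db


def dropout_mask(shape, rate: float, rng: np.random.Generator) -> np.ndarray:
    """Inverted-dropout multiplier: 0 with prob ``rate``, else 1/(1-rate)."""
    if rate <= 0.0:
        return np.ones(shape)
    keep = 1.0 - rate
    return (rng.random(shape) < keep).astype(float) / keep


def softmax_xent(logits: np.ndarray, labels: np.ndarray):
    """Mean cross-entropy over rows; returns (loss, d_logits)."""
    p = softmax(logits, axis=-1)
    n = logits.shape[0]
    idx = np.arange(n)
    eps = 1e-12
    loss = float(-np.mean(np.log(p[idx, labels] + eps)))
    d = p.copy()
    d[idx, labels] -= 1.0
    return loss, d / n


# ---------------------------------------------------------------------------
# Optimizer
# ---------------------------------------------------------------------------

class Adam:
    """Adaptive moment estimation over a flat {name: array} parameter dict."""

    def __init__(self, params: dict[str, np.ndarray], lr: float = 0.001,
                 beta1: float = 0.9, beta2: float = 0.999, eps: float = 1e-8):
        self.params = params
        self.lr = lr
        self.beta1 = beta1
        self.beta2 = beta2
        self.eps = eps
        self.t = 0
        self.m = {k: np.zeros_like(v) for k, v in params.items()}
        self.v = {k: np.zeros_like(v) for k, v in params.items()}

    def step(self, grads: dict[str, np.ndarray]) -> None:
        self.t += 1
        b1, b2 = self.beta1, self.beta2
        for k, g in grads.items():
            p = self.params[k]
            self.m[k] = b1 * self.m[k] + (1 - b1) * g
            self.v[k] = b2 * self.v[k] + (1 - b2) * g * g
            mhat = self.m[k] / (1 - b1 ** self.t)
            vhat = self.v[k] / (1 - b2 ** self.t)
            p -= self.lr * mhat / (np.sqrt(vhat) + self.eps)


def clip_gradients(grads: dict[str, np.ndarray], max_norm: float) -> float:
    """Global-norm gradient clipping in place; returns the pre-clip norm."""
    total = float(np.sqrt(sum(float(np.sum(g * g)) for g in grads.values())))
    if max_norm > 0 and total > max_norm:
        scale = max_norm / (total + 1e-12)
        for g in grads.values():
            g *= scale
    return total
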