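"""Bidirectional LSTM layer with variable-length (masked) sequences.

The backward direction is realised by reversing each sequence *within its
valid length* and running a standard left-to-right cell, so padded frames
never contaminate the states that are read out.  This makes predictions on
a padded batch identical to predictions on the truncated sequences.
"""

from __future__ import annotations

import numpy as np

from .layers import Layer, Parameter


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


class _LSTMCell:
    """One direction of an LSTM layer; gate order (i, f, g, o)."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype=np.float64):
        s = 1.0 / np.sqrt(hidden)
        self.hidden = hidden
        self.Wx = Parameter((rng.uniform(-s, s, (d_in, 4 * hidden))).astype(dtype))
        self.Wh = Parameter((rng.uniform(-s, s, (hidden, 4 * hidden))).astype(dtype))
        b = np.zeros(4 * hidden, dtype=dtype)
        b[hidden:2 * hidden] = 1.0  # forget-gate bias
        self.b = Parameter(b, decay=False)

    def parameters(self):
        return [self.Wx, self.Wh, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        B, T, _ = x.shape
        H = self.hidden
        h = np.zeros((B, H), dtype=x.dtype)
        c = np.zeros((B, H), dtype=x.dtype)
        out = np.empty((B, T, H), dtype=x.dtype)
        self._x = x
        self._cache = []
        for t in range(T):
            a = x[:, t] @ self.Wx.value + h @ self.Wh.value + self.b.value
            i = _sigmoid(a[:, :H])
            f = _sigmoid(a[:, H:2 * H])
            g = np.tanh(a[:, 2 * H:3 * H])
            o = _sigmoid(a[:, 3 * H:])
            c_prev, h_prev = c, h
            c = f * c + i * g
            tc = np.tanh(c)
            h = o * tc
            out[:, t] = h
            self._cache.append((i, f, g, o, c_prev, h_prev, tc))
        return out

    def backward(self, dout: np.ndarray) -> np.ndarray:
        x = self._x
        B, T, _ = x.shape
        H = self.hidden
        dx = np.zeros_like(x)
        dh_next = np.zeros((B, H), dtype=x.dtype)
        dc_next = np.zeros((B, H), dtype=x.dtype)
        for t in range(T - 1, -1, -1):
            i, f, g, o, c_prev, h_prev, tc = self._cache[t]
            dh = dout[:, t] + dh_next
            dc = dc_next + dh * o * (1.0 - tc * tc)
            da = np.empty((B, 4 * H), dtype=x.dtype)
            da[:, :H] = dc * g * i * (1.0 - i)
            da[:, H:2 * H] = dc * c_prev * f * (1.0 - f)
            da[:, 2 * H:3 * H] = dc * i * (1.0 - g * g)
            da[:, 3 * H:] = dh * tc * o * (1.0 - o)
            self.Wx.grad += x[:, t].T @ da
            self.Wh.grad += h_prev.T @ da
            self.b.grad += da.sum(axis=0)
            dx[:, t] = da @ self.Wx.value.T
            dh_next = da @ self.Wh.value.T
            dc_next = dc * f
        return dx


class BiLSTMLayer(Layer):
    """One bidirectional layer; output is (B, T, 2H), zero at padded frames."""

    def __init__(self, d_in: int, hidden: int, rng: np.random.Generator, dtype=np.float64):
        self.hidden = hidden
        self.fwd = _LSTMCell(d_in, hidden, rng, dtype)
        self.bwd = _LSTMCell(d_in, hidden, rng, dtype)

    def parameters(self):
        return self.fwd.parameters() + self.bwd.parameters()

    @staticmethod
    def _reverse_valid(x: np.ndarray, lengths: np.ndarray) -> np.ndarray:
        """Reverse each row within its valid length; padding stays zero.

        The mapping t -> length-1-t is an involution, so the same routine
        scatters reversed quantities back.
        """
        B, T = x.shape[:2]
        t_idx = np.arange(T)[None, :]
        valid = t_idx < lengths[:, None]
        src = np.clip(lengths[:, None] - 1 - t_idx, 0, T - 1)
        rows = np.arange(B)[:, None]
        out = np.where(valid[..., None] if x.ndim == 3 else valid, x[rows, src], 0.0)
        return out

    def forward(self, x: np.ndarray, lengths: np.ndarray):
        """Returns (outputs, h_forward_last, h_backward_at_frame0)."""
        self._lengths = lengths
        B, T, _ = x.shape
        valid = (np.arange(T)[None, :] < lengths[:, None])[..., None]
        hf = self.fwd.forward(x)
        x_rev = self._reverse_valid(x, lengths)
        hb_r = self.bwd.forward(x_rev)
        hb = self._reverse_valid(hb_r, lengths)
        out = np.concatenate([np.where(valid, hf, 0.0), hb], axis=-1)
        rows = np.arange(B)
        last = lengths - 1
        self._shapes = (B, T)
        return out, hf[rows, last].copy(), hb_r[rows, last].copy()

    def backward(self, dout: np.ndarray, dh_last_fwd: np.ndarray | None = None,
                 dh_bwd_at0: np.ndarray | None = None) -> np.ndarray:
        lengths = self._lengths
        B, T = self._shapes
        H = self.hidden
        valid = (np.arange(T)[None, :] < lengths[:, None])[..., None]
        dhf = np.where(valid, dout[..., :H], 0.0)
        dhb = np.where(valid, dout[..., H:], 0.0)
        dhb_r = self._reverse_valid(dhb, lengths)
        rows = np.arange(B)
        last = lengths - 1
        if dh_last_fwd is not None:
            dhf = dhf.copy()
            np.add.at(dhf, (rows, last), dh_last_fwd)
        if dh_bwd_at0 is not None:
            np.add.at(dhb_r, (rows, last), dh_bwd_at0)
        dx = self.fwd.backward(dhf)
        dx_rev = self.bwd.backward(dhb_r)
        return dx + self._reverse_valid(dx_rev, lengths)
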