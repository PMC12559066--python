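"""Feed-forward building blocks with hand-written backward passes."""

from __future__ import annotations

import numpy as np
from scipy.special import ndtr  # standard normal CDF, used by GELU

_MASK_NEG = -1e9  # additive score for masked attention keys; exp underflows to 0


class Parameter:
    """A trainable array with an accumulated gradient.

    ``decay`` marks whether AdamW applies weight decay (matrices yes,
    biases/gains/embeddings no — the usual convention).
    """

    __slots__ = ("value", "grad", "decay")

    def __init__(self, value: np.ndarray, decay: bool = True):
        self.value = value
        self.grad = np.zeros_like(value)
        self.decay = decay


class Layer:
    def parameters(self) -> list[Parameter]:
        return []


def _normal(rng: np.random.Generator, shape, std: float, dtype) -> np.ndarray:
    return (rng.standard_normal(shape) * std).astype(dtype)


class Linear(Layer):
    """Affine map over the trailing dimension; fan-in-scaled init."""

    def __init__(self, d_in: int, d_out: int, rng: np.random.Generator,
                 dtype=np.float64, std: float | None = None):
        if std is None:
            std = (1.0 / d_in) ** 0.5
        self.W = Parameter(_normal(rng, (d_in, d_out), std, dtype))
        self.b = Parameter(np.zeros(d_out, dtype=dtype), decay=False)

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        return x @ self.W.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x2 = self._x.reshape(-1, self._x.shape[-1])
        dy2 = dy.reshape(-1, dy.shape[-1])
        self.W.grad += x2.T @ dy2
        self.b.grad += dy2.sum(axis=0)
        return dy @ self.W.value.T


class Conv1dSame(Layer):
    """Temporal convolution, stride 1, zero same-padding, odd kernel."""

    def __init__(self, c_in: int, c_out: int, rng: np.random.Generator,
                 kernel: int = 3, dtype=np.float64, std: float | None = None):
        assert kernel % 2 == 1, "same padding requires an odd kernel"
        self.kernel = kernel
        if std is None:  # He-style: convolutions here feed ReLUs
            std = (2.0 / (kernel * c_in)) ** 0.5
        self.W = Parameter(_normal(rng, (kernel, c_in, c_out), std, dtype))
        self.b = Parameter(np.zeros(c_out, dtype=dtype), decay=False)

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        # x: (B, T, C_in)
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp = xp
        T = x.shape[1]
        y = self.b.value + sum(
            xp[:, k:k + T] @ self.W.value[k] for k in range(self.kernel)
        )
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        B, T, _ = dy.shape
        p = self.kernel // 2
        dxp = np.zeros_like(self._xp)
        dy2 = dy.reshape(-1, dy.shape[-1])
        for k in range(self.kernel):
            seg = self._xp[:, k:k + T].reshape(-1, self._xp.shape[-1])
            self.W.grad[k] += seg.T @ dy2
            dxp[:, k:k + T] += dy @ self.W.value[k].T
        self.b.grad += dy2.sum(axis=0)
        return dxp[:, p:p + T]


class DepthwiseConv1dSame(Layer):
    """Per-channel temporal convolution (depthwise), zero same-padding."""

    def __init__(self, channels: int, rng: np.random.Generator,
                 kernel: int = 3, dtype=np.float64, std: float = 0.2):
        assert kernel % 2 == 1
        self.kernel = kernel
        self.W = Parameter(_normal(rng, (kernel, channels), std, dtype))
        self.b = Parameter(np.zeros(channels, dtype=dtype), decay=False)

    def parameters(self):
        return [self.W, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        p = self.kernel // 2
        xp = np.pad(x, ((0, 0), (p, p), (0, 0)))
        self._xp = xp
        T = x.shape[1]
        y = self.b.value + sum(
            xp[:, k:k + T] * self.W.value[k] for k in range(self.kernel)
        )
        return y

    def backward(self, dy: np.ndarray) -> np.ndarray:
        T = dy.shape[1]
        p = self.kernel // 2
        dxp = np.zeros_like(self._xp)
        for k in range(self.kernel):
            self.W.grad[k] += (self._xp[:, k:k + T] * dy).sum(axis=(0, 1))
            dxp[:, k:k + T] += dy * self.W.value[k]
        self.b.grad += dy.sum(axis=(0, 1))
        return dxp[:, p:p + T]


class ReLU(Layer):
    def forward(self, x: np.ndarray) -> np.ndarray:
        self._pos = x > 0
        return np.maximum(x, 0)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        return dy * self._pos


class GELU(Layer):
    """Exact Gaussian error linear unit, x * Phi(x)."""

    def forward(self, x: np.ndarray) -> np.ndarray:
        self._x = x
        self._cdf = ndtr(x)
        return x * self._cdf

    def backward(self, dy: np.ndarray) -> np.ndarray:
        x = self._x
        pdf = np.exp(-0.5 * x * x) / np.sqrt(2.0 * np.pi)
        return dy * (self._cdf + x * pdf)


class LayerNorm(Layer):
    def __init__(self, dim: int, dtype=np.float64, eps: float = 1e-5):
        self.eps = eps
        self.g = Parameter(np.ones(dim, dtype=dtype), decay=False)
        self.b = Parameter(np.zeros(dim, dtype=dtype), decay=False)

    def parameters(self):
        return [self.g, self.b]

    def forward(self, x: np.ndarray) -> np.ndarray:
        mu = x.mean(axis=-1, keepdims=True)
        var = x.var(axis=-1, keepdims=True)
        self._inv = 1.0 / np.sqrt(var + self.eps)
        self._xhat = (x - mu) * self._inv
        return self._xhat * self.g.value + self.b.value

    def backward(self, dy: np.ndarray) -> np.ndarray:
        xhat, inv = self._xhat, self._inv
        self.g.grad += (dy * xhat).sum(axis=tuple(range(dy.ndim - 1)))
        self.b.grad += dy.sum(axis=tuple(range(dy.ndim - 1)))
        dxhat = dy * self.g.value
        m = xhat.shape[-1]
        return inv * (
            dxhat
            - dxhat.mean(axis=-1, keepdims=True)
            - xhat * (dxhat * xhat).mean(axis=-1, keepdims=True)
        )


class Dropout(Layer):
    """Inverted dropout; identity when rate is 0 or at inference."""

    def __init__(self, rate: float, rng: np.random.Generator):
        if not (0.0 <= rate < 1.0):
            raise ValueError(f"dropout rate must be in [0, 1), got {rate}")
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._mask = None
            return x
        keep = 1.0 - self.rate
        draw_dtype = np.float32 if x.dtype == np.float32 else np.float64
        u = self.rng.random(x.shape, dtype=draw_dtype)
        mask = (u < keep).astype(x.dtype)
        mask /= np.asarray(keep, dtype=x.dtype)
        self._mask = mask
        return x * mask

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._mask is None:
            return dy
        return dy * self._mask


def softmax(x: np.ndarray, axis: int = -1) -> np.ndarray:
    z = x - x.max(axis=axis, keepdims=True)
    np.exp(z, out=z)
    z /= z.sum(axis=axis, keepdims=True)
    return z


def softmax_cross_entropy(
    logits: np.ndarray, labels: np.ndarray
) -> tuple[float, np.ndarray, np.ndarray]:
    """Mean cross-entropy over a batch.

    Returns (loss, dlogits, probs); dlogits already carries the 1/B factor.
    """
    probs = softmax(logits, axis=-1)
    B = logits.shape[0]
    eps = np.finfo(probs.dtype).tiny
    loss = float(-np.log(probs[np.arange(B), labels] + eps).mean())
    dlogits = probs.copy()
    dlogits[np.arange(B), labels] -= 1.0
    return loss, dlogits / B, probs


class MultiheadSelfAttention(Layer):
    """Masked multi-head self-attention.

    Scores are Q K^T / sqrt(D_q) with D_q = D / heads; invalid key positions
    receive a large negative additive score so they are excluded from the
    row-wise softmax support.  Heads are concatenated and linearly
    recombined.
    """

    def __init__(self, dim: int, heads: int, rng: np.random.Generator,
                 attn_dropout: float = 0.0, proj_dropout: float = 0.0,
                 dtype=np.float64):
        if dim % heads != 0:
            raise ValueError(f"dim {dim} not divisible by heads {heads}")
        self.dim = dim
        self.heads = heads
        self.head_dim = dim // heads
        std = (1.0 / dim) ** 0.5
        self.Wq = Parameter(_normal(rng, (dim, dim), std, dtype))
        self.Wk = Parameter(_normal(rng, (dim, dim), std, dtype))
        self.Wv = Parameter(_normal(rng, (dim, dim), std, dtype))
        self.bq = Parameter(np.zeros(dim, dtype=dtype), decay=False)
        self.bk = Parameter(np.zeros(dim, dtype=dtype), decay=False)
        self.bv = Parameter(np.zeros(dim, dtype=dtype), decay=False)
        self.Wo = Parameter(_normal(rng, (dim, dim), std, dtype))
        self.bo = Parameter(np.zeros(dim, dtype=dtype), decay=False)
        self.attn_drop = Dropout(attn_dropout, rng)
        self.proj_drop = Dropout(proj_dropout, rng)

    def parameters(self):
        return [self.Wq, self.Wk, self.Wv, self.bq, self.bk, self.bv,
                self.Wo, self.bo]

    def _split(self, x: np.ndarray) -> np.ndarray:
        # (B, T, D) -> (B, H, T, Dh)
        B, T, _ = x.shape
        return x.reshape(B, T, self.heads, self.head_dim).transpose(0, 2, 1, 3)

    def _merge(self, x: np.ndarray) -> np.ndarray:
        B, H, T, Dh = x.shape
        return x.transpose(0, 2, 1, 3).reshape(B, T, H * Dh)

    def forward(self, x: np.ndarray, mask: np.ndarray | None, train: bool) -> np.ndarray:
        # x: (B, T, D); mask: (B, T) bool, True = valid
        self._x = x
        q = self._split(x @ self.Wq.value + self.bq.value)
        k = self._split(x @ self.Wk.value + self.bk.value)
        v = self._split(x @ self.Wv.value + self.bv.value)
        scores = q @ k.transpose(0, 1, 3, 2) / np.asarray(np.sqrt(self.head_dim), x.dtype)
        if mask is not None:
            bias = np.where(mask, 0.0, _MASK_NEG).astype(x.dtype)
            scores = scores + bias[:, None, None, :]
        attn = softmax(scores, axis=-1)
        attn_d = self.attn_drop.forward(attn, train)
        ctx = attn_d @ v
        merged = self._merge(ctx)
        out = merged @ self.Wo.value + self.bo.value
        out = self.proj_drop.forward(out, train)
        self._cache = (q, k, v, attn, attn_d, merged)
        return out

    def backward(self, dy: np.ndarray) -> np.ndarray:
        q, k, v, attn, attn_d, merged = self._cache
        x = self._x
        dy = self.proj_drop.backward(dy)
        m2 = merged.reshape(-1, self.dim)
        dy2 = dy.reshape(-1, self.dim)
        self.Wo.grad += m2.T @ dy2
        self.bo.grad += dy2.sum(axis=0)
        dmerged = dy @ self.Wo.value.T
        dctx = self._split(dmerged)
        dattn = dctx @ v.transpose(0, 1, 3, 2)
        dv = attn_d.transpose(0, 1, 3, 2) @ dctx
        dattn = self.attn_drop.backward(dattn)
        # softmax backward (masked keys have attn == 0, so their grads vanish)
        inner = np.einsum("bhtk,bhtk->bht", dattn, attn)[..., None]
        dscores = dattn - inner
        dscores *= attn
        dscores /= np.asarray(np.sqrt(self.head_dim), dscores.dtype)
        dq = dscores @ k
        dk = dscores.transpose(0, 1, 3, 2) @ q
        dx = np.zeros_like(x)
        x2 = x.reshape(-1, self.dim)
        for W, b, dh in ((self.Wq, self.bq, dq), (self.Wk, self.bk, dk), (self.Wv, self.bv, dv)):
            d2 = self._merge(dh).reshape(-1, self.dim)
            W.grad += x2.T @ d2
            b.grad += d2.sum(axis=0)
            dx += d2.reshape(x.shape) @ W.value.T
        return dx


class _DropPath:
    """Stochastic depth on a residual branch (per-sample)."""

    def __init__(self, rate: float, rng: np.random.Generator):
        self.rate = rate
        self.rng = rng

    def forward(self, x: np.ndarray, train: bool) -> np.ndarray:
        if not train or self.rate == 0.0:
            self._keep = None
            return x
        keep = 1.0 - self.rate
        shape = (x.shape[0],) + (1,) * (x.ndim - 1)
        self._keep = (self.rng.random(shape) < keep).astype(x.dtype)
        self._keep /= np.asarray(keep, dtype=x.dtype)
        return x * self._keep

    def backward(self, dy: np.ndarray) -> np.ndarray:
        if self._keep is None:
            return dy
        return dy * self._keep


class TransformerBlock(Layer):
    """Pre-norm residual block: attention sublayer then MLP sublayer.

    ``z_bar = MSA(LN(z)) + z`` followed by ``z_hat = MLP(LN(z_bar)) + z_bar``,
    with dropout on the attention weights / projections and stochastic depth
    ("path dropout") on both residual branches.
    """

    def __init__(self, dim: int, heads: int, mlp_ratio: float,
                 rng: np.random.Generator, attn_dropout: float = 0.0,
                 proj_dropout: float = 0.0, path_dropout: float = 0.0,
                 dtype=np.float64, activation: str = "gelu"):
        hidden = int(round(mlp_ratio * dim))
        self.ln1 = LayerNorm(dim, dtype)
        self.attn = MultiheadSelfAttention(dim, heads, rng, attn_dropout,
                                           proj_dropout, dtype)
        self.path1 = _DropPath(path_dropout, rng)
        self.ln2 = LayerNorm(dim, dtype)
        self.fc1 = Linear(dim, hidden, rng, dtype)
        self.act = GELU() if activation == "gelu" else ReLU()
        self.fc2 = Linear(hidden, dim, rng, dtype)
        self.mlp_drop = Dropout(proj_dropout, rng)
        self.path2 = _DropPath(path_dropout, rng)

    def parameters(self):
        return (self.ln1.parameters() + self.attn.parameters()
                + self.ln2.parameters() + self.fc1.parameters()
                + self.fc2.parameters())

    def forward(self, x: np.ndarray, mask: np.ndarray | None, train: bool) -> np.ndarray:
        h = self.attn.forward(self.ln1.forward(x), mask, train)
        z = x + self.path1.forward(h, train)
        m = self.fc2.forward(self.act.forward(self.fc1.forward(self.ln2.forward(z))))
        m = self.mlp_drop.forward(m, train)
        return z + self.path2.forward(m, train)

    def backward(self, dy: np.ndarray) -> np.ndarray:
        dm = self.mlp_drop.backward(self.path2.backward(dy))
        dz = dy + self.ln2.backward(
            self.fc1.backward(self.act.backward(self.fc2.backward(dm)))
        )
        dh = self.path1.backward(dz)
        return dz + self.ln1.backward(self.attn.backward(dh))
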