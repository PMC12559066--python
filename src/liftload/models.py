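"""Sequence classifiers for lifting-load categories.

Three models share one interface: they consume a :class:`SequenceBatch`
(zero-padded T x 47 feature sequences with a validity mask) and emit class
probabilities.  All three are padding-invariant — masked frames are
zero-filled before every convolution, excluded from the attention softmax
support, and excluded from temporal pooling — so predictions on a padded
batch equal predictions on the truncated sequences.

* :class:`TransformerClassifier` — a two-layer temporal-convolution
  projection (47 -> D, kernel 3, same padding, ReLU between), a learned
  positional embedding, L pre-norm Transformer blocks, masked average
  pooling over time, and a linear head.  The default embedding width is
  four times the input feature dimension (188 for 47 features).
* :class:`CNNClassifier` — depthwise temporal convolution projection,
  two residual convolution blocks, masked average pooling, linear head.
* :class:`LSTMClassifier` — convolutional projection and two bidirectional
  LSTM layers; the head reads the forward hidden state at each row's last
  valid frame concatenated with the backward state at frame 0.

The networks run on NumPy with hand-written backward passes (see
``liftload.nn``); with fixed seeds and single-threaded BLAS, training is
bitwise reproducible.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Sequence

import numpy as np

from .kinematics import N_FEATURES, FeatureSequence
from .nn import (
    BiLSTMLayer,
    Conv1dSame,
    DepthwiseConv1dSame,
    LayerNorm,
    Linear,
    MultiheadSelfAttention,
    Parameter,
    ReLU,
    TransformerBlock,
    softmax,
)


# ---------------------------------------------------------------------------
# configs


@dataclass
class TransformerConfig:
    input_dim: int = N_FEATURES
    embed_dim: int | None = None  # default: 4 x input_dim
    depth: int = 2
    heads: int = 4
    mlp_ratio: float = 4.0
    dropout_attn: float = 0.1
    dropout_proj: float = 0.1
    dropout_path: float = 0.1
    max_len: int = 512
    num_classes: int = 3
    pos_embedding: str = "learned"  # or "sinusoidal"
    head: str = "linear"  # or "mlp"
    activation: str = "gelu"  # block MLP activation; "gelu" or "relu"
    dtype: str = "float64"

    def __post_init__(self) -> None:
        if self.embed_dim is None:
            self.embed_dim = 4 * self.input_dim
        if self.embed_dim % self.heads != 0:
            raise ValueError(
                f"embed_dim {self.embed_dim} must be divisible by heads {self.heads}"
            )
        for r in (self.dropout_attn, self.dropout_proj, self.dropout_path):
            if not (0.0 <= r < 1.0):
                raise ValueError(f"dropout rates must be in [0, 1), got {r}")
        if self.num_classes < 2:
            raise ValueError("num_classes must be >= 2")
        if self.pos_embedding not in ("learned", "sinusoidal"):
            raise ValueError(f"unknown pos_embedding {self.pos_embedding!r}")

    @property
    def head_dim(self) -> int:
        return self.embed_dim // self.heads

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class CNNConfig:
    input_dim: int = N_FEATURES
    width: int = 64
    n_blocks: int = 2
    kernel: int = 3
    num_classes: int = 3
    dtype: str = "float64"

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


@dataclass
class LSTMConfig:
    input_dim: int = N_FEATURES
    hidden: int = 64
    n_layers: int = 2
    num_classes: int = 3
    dtype: str = "float64"

    @property
    def np_dtype(self):
        return np.dtype(self.dtype)


# ---------------------------------------------------------------------------
# batching


@dataclass
class SequenceBatch:
    """Zero-padded feature sequences with a validity mask.

    ``features`` is (B, T_max, input_dim); ``mask`` is (B, T_max) boolean
    with True marking valid frames; masked entries of ``features`` are
    zero-filled.  Every row must contain at least one valid frame.
    """

    features: np.ndarray
    mask: np.ndarray
    labels: np.ndarray | None = None

    def __post_init__(self) -> None:
        if self.features.ndim != 3:
            raise ValueError(f"features must be 3-D, got shape {self.features.shape}")
        if self.mask.shape != self.features.shape[:2]:
            raise ValueError("mask shape must match features (B, T)")
        if not self.mask.any(axis=1).all():
            raise ValueError("every row needs at least one valid frame")

    @property
    def lengths(self) -> np.ndarray:
        return self.mask.sum(axis=1).astype(int)

    @classmethod
    def from_sequences(
        cls,
        sequences: Sequence[FeatureSequence | np.ndarray],
        labels: Sequence[int] | None = None,
        dtype=np.float64,
        pad_to: int | None = None,
    ) -> "SequenceBatch":
        arrays = [s.values if isinstance(s, FeatureSequence) else np.asarray(s) for s in sequences]
        lengths = [a.shape[0] for a in arrays]
        T = pad_to or max(lengths)
        if T < max(lengths):
            raise ValueError(f"pad_to={pad_to} shorter than longest sequence {max(lengths)}")
        B = len(arrays)
        feats = np.zeros((B, T, arrays[0].shape[1]), dtype=dtype)
        mask = np.zeros((B, T), dtype=bool)
        for i, a in enumerate(arrays):
            feats[i, : a.shape[0]] = a
            mask[i, : a.shape[0]] = True
        lab = None if labels is None else np.asarray(labels, dtype=int)
        return cls(features=feats, mask=mask, labels=lab)


@dataclass
class ClassProbabilities:
    """Rows are per-instance probability vectors summing to one."""

    probs: np.ndarray

    def __post_init__(self) -> None:
        if (self.probs < 0).any():
            raise ValueError("probabilities must be non-negative")
        if not np.allclose(self.probs.sum(axis=-1), 1.0, atol=1e-6):
            raise ValueError("probability rows must sum to 1")

    def argmax(self) -> np.ndarray:
        return self.probs.argmax(axis=-1)


def sinusoidal_embedding(max_len: int, dim: int, dtype=np.float64) -> np.ndarray:
    """Fixed sine/cosine positional table (classic Transformer layout)."""
    pos = np.arange(max_len)[:, None].astype(float)
    i = np.arange(dim // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / dim)
    table = np.zeros((max_len, dim))
    table[:, 0::2] = np.sin(angles)
    table[:, 1::2] = np.cos(angles[:, : dim - dim // 2])
    return table.astype(dtype)


# ---------------------------------------------------------------------------
# models


class _ModelBase:
    config: object
    kind: str
    #: optional per-channel (mean, std) fitted on the training set
    input_norm: tuple[np.ndarray, np.ndarray] | None = None

    def parameters(self) -> list[Parameter]:
        raise NotImplementedError

    def forward_logits(self, feats: np.ndarray, mask: np.ndarray, train: bool) -> np.ndarray:
        raise NotImplementedError

    def backward(self, dlogits: np.ndarray) -> None:
        raise NotImplementedError

    def set_input_norm(self, mean: np.ndarray, std: np.ndarray) -> None:
        """Attach per-channel standardisation applied before the network.

        Position/angle channels are two orders of magnitude larger than the
        per-frame velocity/acceleration channels; standardising to unit
        variance makes all channels visible to the optimiser.
        """
        dt = self.config.np_dtype
        self.input_norm = (np.asarray(mean, dtype=dt), np.asarray(std, dtype=dt))

    def normalize_input(self, feats: np.ndarray, mask: np.ndarray) -> np.ndarray:
        if self.input_norm is None:
            return feats
        mean, std = self.input_norm
        return (feats - mean) / std * mask[..., None]

    def forward(self, batch: SequenceBatch, train: bool = False) -> ClassProbabilities:
        feats = batch.features.astype(self.config.np_dtype, copy=False)
        logits = self.forward_logits(self.normalize_input(feats, batch.mask), batch.mask, train)
        return ClassProbabilities(probs=softmax(logits, axis=-1))


class TransformerClassifier(_ModelBase):
    kind = "transformer"

    def __init__(self, config: TransformerConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        c, dt = config, config.np_dtype
        self.conv1 = Conv1dSame(c.input_dim, c.embed_dim, self.rng, dtype=dt)
        self.relu = ReLU()
        self.conv2 = Conv1dSame(c.embed_dim, c.embed_dim, self.rng, dtype=dt)
        if c.pos_embedding == "learned":
            self.pos = Parameter(
                (self.rng.standard_normal((c.max_len, c.embed_dim)) * 0.02).astype(dt),
                decay=False,
            )
            self._pos_fixed = None
        else:
            self.pos = None
            self._pos_fixed = sinusoidal_embedding(c.max_len, c.embed_dim, dt)
        self.blocks = [
            TransformerBlock(
                c.embed_dim, c.heads, c.mlp_ratio, self.rng,
                attn_dropout=c.dropout_attn, proj_dropout=c.dropout_proj,
                path_dropout=c.dropout_path, dtype=dt, activation=c.activation,
            )
            for _ in range(c.depth)
        ]
        self.norm = LayerNorm(c.embed_dim, dtype=dt)
        if c.head == "linear":
            self.head = Linear(c.embed_dim, c.num_classes, self.rng, dtype=dt)
            self.head_hidden = None
        else:
            self.head_hidden = Linear(c.embed_dim, c.embed_dim, self.rng, dtype=dt)
            self.head_act = ReLU()
            self.head = Linear(c.embed_dim, c.num_classes, self.rng, dtype=dt)

    def parameters(self) -> list[Parameter]:
        ps = self.conv1.parameters() + self.conv2.parameters()
        if self.pos is not None:
            ps.append(self.pos)
        for b in self.blocks:
            ps += b.parameters()
        ps += self.norm.parameters()
        if self.head_hidden is not None:
            ps += self.head_hidden.parameters()
        ps += self.head.parameters()
        return ps

    # -- embedding stage (projection convolutions + positional embedding)

    def embed(self, feats: np.ndarray, mask: np.ndarray) -> np.ndarray:
        """Project a (B, T, input_dim) batch to (B, T, D) and add positions."""
        T = feats.shape[1]
        if T > self.config.max_len:
            raise ValueError(f"sequence length {T} exceeds max_len {self.config.max_len}")
        m = mask[..., None].astype(feats.dtype)
        self._m = m
        x = feats * m
        x = self.conv1.forward(x) * m
        x = self.relu.forward(x)
        x = self.conv2.forward(x) * m
        table = self.pos.value if self.pos is not None else self._pos_fixed
        return x + table[:T]

    def _embed_backward(self, dx: np.ndarray) -> None:
        if self.pos is not None:
            self.pos.grad[: dx.shape[1]] += dx.sum(axis=0)
        dx = self.conv2.backward(dx * self._m)
        dx = self.relu.backward(dx)
        dx = self.conv1.backward(dx * self._m)
        # gradient w.r.t. the input features is not needed

    def forward_logits(self, feats: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        x = self.embed(feats, mask)
        for blk in self.blocks:
            x = blk.forward(x, mask, train)
        x = self.norm.forward(x)
        m = self._m
        counts = m.sum(axis=1)
        self._pool = (m, counts)
        pooled = (x * m).sum(axis=1) / counts
        if self.head_hidden is not None:
            pooled = self.head_act.forward(self.head_hidden.forward(pooled))
        return self.head.forward(pooled)

    def backward(self, dlogits: np.ndarray) -> None:
        dpooled = self.head.backward(dlogits)
        if self.head_hidden is not None:
            dpooled = self.head_hidden.backward(self.head_act.backward(dpooled))
        m, counts = self._pool
        dx = (dpooled / counts)[:, None, :] * m
        dx = self.norm.backward(dx)
        for blk in reversed(self.blocks):
            dx = blk.backward(dx)
        self._embed_backward(dx)


class CNNClassifier(_ModelBase):
    """1D residual network baseline with a depthwise-convolution projection."""

    kind = "cnn"

    def __init__(self, config: CNNConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        c, dt = config, config.np_dtype
        self.dw = DepthwiseConv1dSame(c.input_dim, self.rng, kernel=c.kernel, dtype=dt)
        self.pw = Linear(c.input_dim, c.width, self.rng, dtype=dt)
        self.proj_relu = ReLU()
        self.blocks = []
        for _ in range(c.n_blocks):
            self.blocks.append(
                (
                    Conv1dSame(c.width, c.width, self.rng, kernel=c.kernel, dtype=dt),
                    ReLU(),
                    Conv1dSame(c.width, c.width, self.rng, kernel=c.kernel, dtype=dt),
                )
            )
        self.head = Linear(c.width, c.num_classes, self.rng, dtype=dt)

    def parameters(self) -> list[Parameter]:
        ps = self.dw.parameters() + self.pw.parameters()
        for conv_a, _, conv_b in self.blocks:
            ps += conv_a.parameters() + conv_b.parameters()
        ps += self.head.parameters()
        return ps

    def forward_logits(self, feats: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        m = mask[..., None].astype(feats.dtype)
        self._m = m
        x = feats * m
        x = self.dw.forward(x) * m
        x = self.proj_relu.forward(self.pw.forward(x)) * m
        for conv_a, relu, conv_b in self.blocks:
            h = relu.forward(conv_a.forward(x) * m)
            x = x + conv_b.forward(h) * m
        counts = m.sum(axis=1)
        self._counts = counts
        pooled = (x * m).sum(axis=1) / counts
        return self.head.forward(pooled)

    def backward(self, dlogits: np.ndarray) -> None:
        m = self._m
        dpooled = self.head.backward(dlogits)
        dx = (dpooled / self._counts)[:, None, :] * m
        for conv_a, relu, conv_b in reversed(self.blocks):
            dh = conv_b.backward(dx * m)
            dx = dx + conv_a.backward(relu.backward(dh) * m)
        dx = self.pw.backward(self.proj_relu.backward(dx * m))
        self.dw.backward(dx * m)


class LSTMClassifier(_ModelBase):
    """Two bidirectional LSTM layers over a convolutional projection."""

    kind = "lstm"

    def __init__(self, config: LSTMConfig, seed: int = 0):
        self.config = config
        self.rng = np.random.default_rng(seed)
        c, dt = config, config.np_dtype
        self.proj = Conv1dSame(c.input_dim, c.hidden, self.rng, dtype=dt)
        self.proj_relu = ReLU()
        self.layers = []
        d_in = c.hidden
        for _ in range(c.n_layers):
            self.layers.append(BiLSTMLayer(d_in, c.hidden, self.rng, dtype=dt))
            d_in = 2 * c.hidden
        self.head = Linear(2 * c.hidden, c.num_classes, self.rng, dtype=dt)

    def parameters(self) -> list[Parameter]:
        ps = self.proj.parameters()
        for layer in self.layers:
            ps += layer.parameters()
        ps += self.head.parameters()
        return ps

    def forward_logits(self, feats: np.ndarray, mask: np.ndarray, train: bool = False) -> np.ndarray:
        m = mask[..., None].astype(feats.dtype)
        lengths = mask.sum(axis=1).astype(int)
        self._m = m
        x = feats * m
        x = self.proj_relu.forward(self.proj.forward(x) * m)
        h_last = h_first = None
        for layer in self.layers:
            x, h_last, h_first = layer.forward(x, lengths)
        state = np.concatenate([h_last, h_first], axis=-1)
        return self.head.forward(state)

    def backward(self, dlogits: np.ndarray) -> None:
        H = self.config.hidden
        dstate = self.head.backward(dlogits)
        dh_last, dh_first = dstate[:, :H], dstate[:, H:]
        # only the top layer receives gradients, through its read-out states
        B, T = self.layers[-1]._shapes
        dout = np.zeros((B, T, 2 * H), dtype=self.config.np_dtype)
        dx = self.layers[-1].backward(dout, dh_last, dh_first)
        for layer in reversed(self.layers[:-1]):
            dx = layer.backward(dx)
        m = self._m
        self.proj.backward(self.proj_relu.backward(dx) * m)


_MODEL_KINDS = {
    "transformer": (TransformerClassifier, TransformerConfig),
    "cnn": (CNNClassifier, CNNConfig),
    "lstm": (LSTMClassifier, LSTMConfig),
}


def build_model(kind: str, config=None, seed: int = 0, **config_kwargs):
    """Instantiate a classifier by kind with a fresh config if none given."""
    if kind not in _MODEL_KINDS:
        raise ValueError(f"unknown model kind {kind!r}; expected one of {sorted(_MODEL_KINDS)}")
    cls, cfg_cls = _MODEL_KINDS[kind]
    if config is None:
        config = cfg_cls(**config_kwargs)
    return cls(config, seed=seed)


# ---------------------------------------------------------------------------
# functional forms mirroring the pipeline stages


def project_embed(batch: SequenceBatch, model: TransformerClassifier) -> np.ndarray:
    """Embedding stage of the Transformer: conv projection + positions."""
    feats = batch.features.astype(model.config.np_dtype, copy=False)
    return model.embed(feats, batch.mask)


def self_attention(Z: np.ndarray, config: TransformerConfig, seed: int = 0,
                   mask: np.ndarray | None = None) -> np.ndarray:
    """Single-sequence masked self-attention with freshly seeded weights."""
    layer = MultiheadSelfAttention(config.embed_dim, config.heads,
                                   np.random.default_rng(seed),
                                   dtype=config.np_dtype)
    if mask is not None and not mask.any():
        raise ValueError("mask excludes every position")
    out = layer.forward(Z[None, ...], None if mask is None else mask[None, :], train=False)
    return out[0]


def transformer_block(Z: np.ndarray, config: TransformerConfig, seed: int = 0,
                      mask: np.ndarray | None = None) -> np.ndarray:
    """One freshly initialised pre-norm block applied to a single sequence."""
    blk = TransformerBlock(config.embed_dim, config.heads, config.mlp_ratio,
                           np.random.default_rng(seed), dtype=config.np_dtype)
    out = blk.forward(Z[None, ...], None if mask is None else mask[None, :], train=False)
    return out[0]


def transformer_forward(batch: SequenceBatch, model_or_config, train_mode: bool = False,
                        seed: int = 0) -> ClassProbabilities:
    model = (model_or_config if isinstance(model_or_config, TransformerClassifier)
             else TransformerClassifier(model_or_config, seed=seed))
    return model.forward(batch, train=train_mode)


def cnn_forward(batch: SequenceBatch, model_or_config, train_mode: bool = False,
                seed: int = 0) -> ClassProbabilities:
    model = (model_or_config if isinstance(model_or_config, CNNClassifier)
             else CNNClassifier(model_or_config, seed=seed))
    return model.forward(batch, train=train_mode)


def lstm_forward(batch: SequenceBatch, model_or_config, train_mode: bool = False,
                 seed: int = 0) -> ClassProbabilities:
    model = (model_or_config if isinstance(model_or_config, LSTMClassifier)
             else LSTMClassifier(model_or_config, seed=seed))
    return model.forward(batch, train=train_mode)


# ---------------------------------------------------------------------------
# checkpoints


def save_checkpoint(model: _ModelBase, path: str | Path) -> None:
    """Persist kind + config + weights (+ RNG state) to an .npz file."""
    path = Path(path)
    arrays = {f"param_{i}": p.value for i, p in enumerate(model.parameters())}
    if model.input_norm is not None:
        arrays["input_norm_mean"], arrays["input_norm_std"] = model.input_norm
    meta = {
        "kind": model.kind,
        "config": asdict(model.config),
        "rng_state": model.rng.bit_generator.state,
    }
    arrays["meta_json"] = np.frombuffer(json.dumps(meta).encode(), dtype=np.uint8)
    np.savez(path, **arrays)


def load_checkpoint(path: str | Path) -> _ModelBase:
    data = np.load(Path(path))
    meta = json.loads(bytes(data["meta_json"]).decode())
    model = build_model(meta["kind"], config=None, seed=0, **meta["config"])
    for i, p in enumerate(model.parameters()):
        p.value[...] = data[f"param_{i}"]
    if "input_norm_mean" in data:
        model.set_input_norm(data["input_norm_mean"], data["input_norm_std"])
    model.rng.bit_generator.state = meta["rng_state"]
    return model
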