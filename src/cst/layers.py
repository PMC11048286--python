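"""Building blocks of the convolutional sparse transformer.

Each block exists in two forms:

* a *batched autodiff forward* operating on :class:`~cst.autodiff.Tensor`
  values of shape ``[N, L, d]`` — these are what training uses;
* a thin *functional* NumPy wrapper with the single-instance signature
  (``[T, C]`` or ``[L, d]`` in, array out) for direct inspection and testing.

The science in brief: a per-electrode sigmoid gate computed from time-pooled
channel statistics rescales the raw signal (spatial channel attention); a
1-D convolution embeds the channels into ``d_model`` features; encoder
layers apply multi-head self-attention — either dense, or *equidistant
sparse* where only ``u = ceil(c * ln L)`` query positions attend over all
keys and every other ("lazy") position is filled with the column mean of V;
a distilling ``MaxPool(ELU(Conv1d(.)))`` stage halves the temporal length
after an encoder layer; a mean-pool + affine head emits class logits.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np

from .autodiff import Tensor, gather_rows, row_update, unfold
from .exceptions import ParameterError

__all__ = [
    "select_active_queries", "dense_attention", "sparse_attention",
    "channel_attention", "token_embed", "multi_head", "distill_forward",
    "predict_head", "pair_counter", "distill_output_length",
    "ChannelAttentionParams", "TokenEmbedParams", "AttentionBlock",
    "DistillLayerParams", "PredictHeadParams",
]

_DTYPE = np.float32
_LN_EPS = 1e-5


# ---------------------------------------------------------------------------
# Query-key pair accounting
# ---------------------------------------------------------------------------

class PairCounter:
    """Counts query-key dot products per attention layer call.

    Counts are at the sequence level (pairs per head per instance): a dense
    layer over length L records L*L, a sparse layer with u active queries
    records u*L.  The ratio of these two numbers is the complexity saving of
    the sparse design, e.g. 7/1024 at L = 1024.
    """

    def __init__(self):
        self.layers: List[Tuple[str, int]] = []

    def reset(self):
        self.layers = []

    def record(self, kind: str, n_pairs: int):
        self.layers.append((kind, int(n_pairs)))

    @property
    def total(self) -> int:
        return sum(n for _, n in self.layers)


pair_counter = PairCounter()


# ---------------------------------------------------------------------------
# Active-query selection
# ---------------------------------------------------------------------------

def select_active_queries(L: int, c: float = 1.0) -> np.ndarray:
    """Equidistant active-query indices for sparse attention.

    ``u = max(1, ceil(c * ln L))`` (capped at L) indices placed by
    ``idx_k = floor(k * L / u)`` — deterministic, content-independent and
    identical across heads, starting at position 0.
    """
    if L < 1:
        raise ParameterError("L must be >= 1")
    if c <= 0:
        raise ParameterError("query factor c must be > 0")
    u = max(1, math.ceil(c * math.log(L))) if L > 1 else 1
    u = min(u, L)
    return np.array([(k * L) // u for k in range(u)], dtype=np.int64)


# ---------------------------------------------------------------------------
# Functional attention (single instance, NumPy)
# ---------------------------------------------------------------------------

def dense_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray) -> np.ndarray:
    """softmax(Q K^T / sqrt(d)) V for 2-D Q, K, V."""
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    if Q.shape[1] != K.shape[1] or K.shape[0] != V.shape[0]:
        raise ParameterError("Q/K/V inner dimensions disagree")
    scores = Q @ K.T / math.sqrt(Q.shape[1])
    scores -= scores.max(axis=1, keepdims=True)
    w = np.exp(scores)
    w /= w.sum(axis=1, keepdims=True)
    pair_counter.record("dense", Q.shape[0] * K.shape[0])
    return w @ V


def sparse_attention(Q: np.ndarray, K: np.ndarray, V: np.ndarray,
                     active) -> np.ndarray:
    """Equidistant sparse attention with lazy-query mean fill.

    Rows listed in ``active`` receive full attention over every key; every
    other row is assigned the column mean of V exactly (not an
    approximation — the lazy fill *is* the mean).
    """
    Q, K, V = (np.asarray(a, dtype=np.float64) for a in (Q, K, V))
    active = np.asarray(active, dtype=np.int64)
    L = Q.shape[0]
    if len(np.unique(active)) != len(active):
        raise ParameterError("active indices must be unique")
    if len(active) and (active.min() < 0 or active.max() >= L):
        raise ParameterError("active indices out of range")
    out = np.broadcast_to(V.mean(axis=0), (L, V.shape[1])).copy()
    if len(active):
        scores = Q[active] @ K.T / math.sqrt(Q.shape[1])
        scores -= scores.max(axis=1, keepdims=True)
        w = np.exp(scores)
        w /= w.sum(axis=1, keepdims=True)
        out[active] = w @ V
    pair_counter.record("sparse", len(active) * K.shape[0])
    return out


# ---------------------------------------------------------------------------
# Parameter containers
# ---------------------------------------------------------------------------

def _uniform(rng, shape, fan_in) -> Tensor:
    bound = 1.0 / math.sqrt(max(fan_in, 1))
    return Tensor(rng.uniform(-bound, bound, size=shape).astype(_DTYPE),
                  requires_grad=True)


@dataclass
class ChannelAttentionParams:
    """Shared two-layer MLP of the channel gate: W0 squeezes C -> C/r,
    W1 expands back; no biases, matching the gate formula
    ``sigmoid(W1 W0 x_avg + W1 W0 x_max)``."""

    W0: Tensor  # [hidden, C]
    W1: Tensor  # [C, hidden]

    @classmethod
    def init(cls, rng, C: int, reduction: int) -> "ChannelAttentionParams":
        hidden = max(1, C // reduction)
        return cls(W0=_uniform(rng, (hidden, C), C),
                   W1=_uniform(rng, (C, hidden), hidden))

    def params(self):
        return [self.W0, self.W1]


@dataclass
class TokenEmbedParams:
    """Channel-to-feature embedding: conv1d (kernel 3, pad 1) C -> d_model,
    optionally plus sinusoidal position codes."""

    weight: Tensor  # [K*C, d_model]
    bias: Tensor    # [d_model]
    kernel: int
    use_position: bool

    @classmethod
    def init(cls, rng, C: int, d_model: int, kernel: int = 3,
             use_position: bool = True) -> "TokenEmbedParams":
        fan_in = kernel * C
        return cls(weight=_uniform(rng, (fan_in, d_model), fan_in),
                   bias=_uniform(rng, (d_model,), fan_in),
                   kernel=kernel, use_position=use_position)

    def params(self):
        return [self.weight, self.bias]


@dataclass
class AttentionBlock:
    """One encoder layer: Q/K/V/output projections, residual + layer norm,
    and the position-wise feed-forward sublayer (inherited from the vanilla
    transformer for everything the sparse design does not override)."""

    Wq: Tensor
    bq: Tensor
    Wk: Tensor
    bk: Tensor
    Wv: Tensor
    bv: Tensor
    Wo: Tensor
    bo: Tensor
    ln1_g: Tensor
    ln1_b: Tensor
    W1: Tensor
    b1: Tensor
    W2: Tensor
    b2: Tensor
    ln2_g: Tensor
    ln2_b: Tensor
    n_heads: int

    @classmethod
    def init(cls, rng, d_model: int, d_ff: int, n_heads: int) -> "AttentionBlock":
        if d_model % n_heads:
            raise ParameterError("d_model must be divisible by n_heads")
        mk = lambda fi, shape: _uniform(rng, shape, fi)
        ones = lambda: Tensor(np.ones(d_model, dtype=_DTYPE), requires_grad=True)
        zeros = lambda: Tensor(np.zeros(d_model, dtype=_DTYPE), requires_grad=True)
        return cls(
            Wq=mk(d_model, (d_model, d_model)), bq=mk(d_model, (d_model,)),
            Wk=mk(d_model, (d_model, d_model)), bk=mk(d_model, (d_model,)),
            Wv=mk(d_model, (d_model, d_model)), bv=mk(d_model, (d_model,)),
            Wo=mk(d_model, (d_model, d_model)), bo=mk(d_model, (d_model,)),
            ln1_g=ones(), ln1_b=zeros(),
            W1=mk(d_model, (d_model, d_ff)), b1=mk(d_model, (d_ff,)),
            W2=mk(d_ff, (d_ff, d_model)), b2=mk(d_ff, (d_model,)),
            ln2_g=ones(), ln2_b=zeros(),
            n_heads=n_heads,
        )

    def params(self):
        return [self.Wq, self.bq, self.Wk, self.bk, self.Wv, self.bv,
                self.Wo, self.bo, self.ln1_g, self.ln1_b,
                self.W1, self.b1, self.W2, self.b2, self.ln2_g, self.ln2_b]


@dataclass
class DistillLayerParams:
    """Distilling stage: conv1d d_model -> d_model (kernel ``conv_kernel``,
    'same' padding), ELU, then max-pool with the given geometry."""

    weight: Tensor  # [K*d_model, d_model]
    bias: Tensor    # [d_model]
    conv_kernel: int
    pool_kernel: int
    pool_stride: int
    pool_pad: int

    @classmethod
    def init(cls, rng, d_model: int, conv_kernel: int = 3,
             pool_kernel: int = 3, pool_stride: int = 2,
             pool_pad: int = 1) -> "DistillLayerParams":
        fan_in = conv_kernel * d_model
        return cls(weight=_uniform(rng, (fan_in, d_model), fan_in),
                   bias=_uniform(rng, (d_model,), fan_in),
                   conv_kernel=conv_kernel, pool_kernel=pool_kernel,
                   pool_stride=pool_stride, pool_pad=pool_pad)

    def params(self):
        return [self.weight, self.bias]


@dataclass
class PredictHeadParams:
    W: Tensor  # [d_model, n_classes]
    b: Tensor

    @classmethod
    def init(cls, rng, d_model: int, n_classes: int) -> "PredictHeadParams":
        return cls(W=_uniform(rng, (d_model, n_classes), d_model),
                   b=_uniform(rng, (n_classes,), d_model))

    def params(self):
        return [self.W, self.b]


# ---------------------------------------------------------------------------
# Batched autodiff forwards
# ---------------------------------------------------------------------------

def _layer_norm(x: Tensor, g: Tensor, b: Tensor) -> Tensor:
    mu = x.mean(axis=-1, keepdims=True)
    xc = x - mu
    var = (xc * xc).mean(axis=-1, keepdims=True)
    return xc * (var + _LN_EPS) ** -0.5 * g + b


def _dropout(x: Tensor, rate: float, rng, train: bool) -> Tensor:
    if not train or rate <= 0 or rng is None:
        return x
    mask = (rng.random(x.data.shape) >= rate) / (1.0 - rate)
    return x * Tensor(mask.astype(x.data.dtype))


def channel_attention_batch(X: Tensor, p: ChannelAttentionParams) -> Tensor:
    """Gate each channel of ``X`` [N, T, C] by its attention weight."""
    if X.shape[-1] != p.W0.shape[1]:
        raise ParameterError(
            f"channel count {X.shape[-1]} does not match params "
            f"(C={p.W0.shape[1]})")
    avg = X.mean(axis=1)           # [N, C]
    mx = X.max(axis=1)             # [N, C]
    mlp = lambda v: (v @ p.W0.swapaxes(0, 1)) @ p.W1.swapaxes(0, 1)
    gate = (mlp(avg) + mlp(mx)).sigmoid()      # [N, C], each entry in (0,1)
    N, C = gate.shape
    return X * gate.reshape(N, 1, C)


def _sinusoid_position_codes(L: int, d_model: int) -> np.ndarray:
    pos = np.arange(L)[:, None].astype(np.float64)
    i = np.arange(d_model // 2)[None, :]
    angles = pos / np.power(10000.0, 2 * i / d_model)
    pe = np.zeros((L, d_model))
    pe[:, 0::2] = np.sin(angles)
    pe[:, 1::2] = np.cos(angles[:, : d_model - d_model // 2])
    return pe


def _conv1d(x: Tensor, weight: Tensor, bias: Tensor, kernel: int) -> Tensor:
    pad = (kernel - 1) // 2
    cols = unfold(x, kernel, 1, pad, fill=0.0)          # [N, L, K, C]
    N, L, K, C = cols.shape
    return cols.reshape(N, L, K * C) @ weight + bias


def token_embed_batch(X: Tensor, p: TokenEmbedParams) -> Tensor:
    """Embed [N, T, C] into [N, T, d_model]; add position codes if enabled."""
    h = _conv1d(X, p.weight, p.bias, p.kernel)
    if p.use_position:
        pe = _sinusoid_position_codes(h.shape[1], h.shape[2])
        h = h + Tensor(pe.astype(h.data.dtype))
    return h


def multi_head_batch(X: Tensor, block: AttentionBlock, sparse: bool,
                     c: float = 1.0, dropout: float = 0.0,
                     rng=None, train: bool = False) -> Tensor:
    """One encoder layer on [N, L, d_model]: multi-head (sparse or dense)
    attention with residual + layer norm, then the feed-forward sublayer."""
    N, L, D = X.shape
    h = block.n_heads
    dh = D // h
    scale = 1.0 / math.sqrt(dh)

    def heads(t: Tensor) -> Tensor:
        return t.reshape(N, L, h, dh).transpose((0, 2, 1, 3))  # [N,h,L,dh]

    Q = heads(X @ block.Wq + block.bq)
    K = heads(X @ block.Wk + block.bk)
    V = heads(X @ block.Wv + block.bv)

    if sparse:
        active = select_active_queries(L, c)
        u = len(active)
        pair_counter.record("sparse", u * L)
        Qa = gather_rows(Q, active, axis=2) * scale           # [N,h,u,dh]
        w = (Qa @ K.swapaxes(-1, -2)).softmax(axis=-1)
        attended = w @ V                                       # [N,h,u,dh]
        lazy = V.mean(axis=2, keepdims=True) + Tensor(
            np.zeros((N, h, L, dh), dtype=X.data.dtype))       # broadcast fill
        ctx = row_update(lazy, attended, active, axis=2)
    else:
        pair_counter.record("dense", L * L)
        w = ((Q * scale) @ K.swapaxes(-1, -2)).softmax(axis=-1)
        ctx = w @ V

    merged = ctx.transpose((0, 2, 1, 3)).reshape(N, L, D)
    out = _dropout(merged @ block.Wo + block.bo, dropout, rng, train)
    h1 = _layer_norm(X + out, block.ln1_g, block.ln1_b)
    ffn = (h1 @ block.W1 + block.b1).relu() @ block.W2 + block.b2
    ffn = _dropout(ffn, dropout, rng, train)
    return _layer_norm(h1 + ffn, block.ln2_g, block.ln2_b)


def distill_output_length(L: int, pool_kernel: int = 3, pool_stride: int = 2,
                          pool_pad: int = 1) -> int:
    """Temporal length after one distilling layer.

    ``L' = floor((L + 2*pad - kernel) / stride) + 1``; with the default
    kernel 3 / stride 2 / pad 1 geometry this is ``ceil(L / 2)`` — exactly
    ``L/2`` for even L.
    """
    out = (L + 2 * pool_pad - pool_kernel) // pool_stride + 1
    if out < 1:
        raise ParameterError(f"length {L} too short for pooling geometry")
    return out


def distill_batch(X: Tensor, p: DistillLayerParams) -> Tensor:
    """MaxPool(ELU(Conv1d(X))) along time: [N, L, d] -> [N, L', d]."""
    conv = _conv1d(X, p.weight, p.bias, p.conv_kernel)
    act = conv.elu()
    pooled = unfold(act, p.pool_kernel, p.pool_stride, p.pool_pad,
                    fill=-np.inf)
    return pooled.max(axis=2)


def predict_head_batch(H: Tensor, p: PredictHeadParams) -> Tensor:
    """Mean over remaining time positions, then affine map to logits."""
    return H.mean(axis=1) @ p.W + p.b


# ---------------------------------------------------------------------------
# Functional single-instance wrappers
# ---------------------------------------------------------------------------

def _single(fn, X, *args, **kwargs) -> np.ndarray:
    t = Tensor(np.asarray(X)[None, ...])
    return np.asarray(fn(t, *args, **kwargs).data[0])


def channel_attention(X: np.ndarray, params: ChannelAttentionParams) -> np.ndarray:
    """Apply the channel gate to a single [T, C] epoch."""
    return _single(channel_attention_batch, X, params)


def token_embed(X: np.ndarray, params: TokenEmbedParams) -> np.ndarray:
    """Embed a single [T, C] epoch into [T, d_model]."""
    return _single(token_embed_batch, X, params)


def multi_head(X: np.ndarray, block: AttentionBlock, sparse: bool = False,
               c: float = 1.0) -> np.ndarray:
    """Run one encoder layer on a single [L, d_model] sequence."""
    return _single(multi_head_batch, X, block, sparse, c)


def distill_forward(X: np.ndarray, params: DistillLayerParams) -> np.ndarray:
    """Distill a single [L, d_model] sequence to [L', d_model]."""
    return _single(distill_batch, X, params)


def predict_head(H: np.ndarray, params: PredictHeadParams) -> np.ndarray:
    """Logits for a single [L, d_model] feature sequence."""
    return _single(predict_head_batch, H, params)
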