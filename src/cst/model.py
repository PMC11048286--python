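"""The convolutional sparse transformer: configuration, stack assembly,
forward pass, and a statsmodels-style model/results pair for fitting.

Layer plan.  With the default configuration (3 sparse + 3 full attention
layers, 5 convolutional + 5 pooling layers) the encoder interleaves a
distilling stage after each of the first five attention layers and none
after the last:

    channel gate -> embed -> [sparse, distill] x3 -> [full, distill] x2 -> full
                 -> mean pool -> logits

so an 8 s epoch at 256 Hz (T = 2048) leaves the encoder at length 64.  The
plan is a pure function of the configuration; any other interleaving can be
obtained by overriding ``layer_plan``.
"""

from __future__ import annotations

import io as _io
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import List, Optional, Sequence, Tuple

import numpy as np

from .autodiff import Adam, Tensor, cross_entropy
from .exceptions import (ConfigurationError, DataError, ParameterError,
                         TrainingDivergedError)
from .io import EpochSet
from . import layers as L

__all__ = ["ModelConfig", "TrainConfig", "EncoderStack", "model_forward",
           "ConvSparseTransformer", "CSTResults", "save_checkpoint",
           "load_checkpoint"]


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ModelConfig:
    """All architecture hyperparameters.

    Defaults reproduce the full-scale reference configuration: 3 sparse and
    3 full attention layers, 8 heads, d_model 128, d_ff 512, 5 convolution
    and 5 max-pooling (distilling) layers.  ``query_factor`` scales the
    sparse active-query budget ``u = ceil(query_factor * ln L)``;
    ``channel_reduction`` is the squeeze ratio r of the channel-gate MLP
    (default ``max(1, C // 2)``, chosen so that even 4-channel recordings
    keep a non-trivial bottleneck).  The three ``use_*`` flags form the
    ablation switchboard.
    """

    in_channels: int
    n_classes: int
    n_sparse_layers: int = 3
    n_full_layers: int = 3
    n_heads: int = 8
    d_model: int = 128
    d_ff: int = 512
    n_conv_layers: int = 5
    n_pool_layers: int = 5
    query_factor: float = 1.0
    channel_reduction: Optional[int] = None
    dropout: float = 0.1
    pool_kernel: int = 3
    pool_stride: int = 2
    pool_pad: int = 1
    conv_kernel: int = 3
    use_channel_attention: bool = True
    use_sparse_attention: bool = True
    use_distillation: bool = True
    use_position_encoding: bool = True
    seed: int = 0

    def __post_init__(self):
        if self.in_channels < 1 or self.n_classes < 2:
            raise ConfigurationError("need in_channels >= 1 and n_classes >= 2")
        if self.d_model % self.n_heads:
            raise ConfigurationError(
                f"d_model={self.d_model} not divisible by n_heads={self.n_heads}")
        if self.n_pool_layers != self.n_conv_layers:
            raise ConfigurationError(
                "n_pool_layers must equal n_conv_layers (one pool per conv)")
        if self.query_factor <= 0:
            raise ConfigurationError("query_factor must be > 0")
        if self.channel_reduction is not None and self.channel_reduction < 1:
            raise ConfigurationError("channel_reduction must be >= 1")

    @property
    def reduction(self) -> int:
        if self.channel_reduction is not None:
            return self.channel_reduction
        return max(1, self.in_channels // 2)

    @property
    def n_attention_layers(self) -> int:
        return self.n_sparse_layers + self.n_full_layers

    def layer_plan(self) -> List[Tuple[str, bool]]:
        """(kind, distill_after) per encoder layer: sparse layers first,
        a distilling stage after each of the first ``n_pool_layers``
        attention layers."""
        kinds = (["sparse"] * self.n_sparse_layers
                 + ["full"] * self.n_full_layers)
        if not self.use_sparse_attention:
            kinds = ["full"] * len(kinds)
        n_distill = self.n_pool_layers if self.use_distillation else 0
        if n_distill > len(kinds):
            raise ConfigurationError(
                f"{n_distill} distill layers cannot follow only "
                f"{len(kinds)} attention layers")
        return [(k, i < n_distill) for i, k in enumerate(kinds)]

    def min_input_length(self) -> int:
        """Smallest T accepted by :func:`model_forward`.

        The distilling stack halves the length once per pooling layer, so
        the strict-halving budget requires ``T >= 2 ** n_pool_layers`` when
        distillation is on.
        """
        return 2 ** self.n_pool_layers if self.use_distillation else 1

    @classmethod
    def from_tuple(cls, tup: Sequence[float], in_channels: int,
                   n_classes: int, **kwargs) -> "ModelConfig":
        """Build from the sensitivity-sweep layout
        [n_sparse, n_full, n_conv, n_pool, d_ff, d_model, n_heads]."""
        if len(tup) != 7:
            raise ConfigurationError("hyperparameter tuple must have 7 entries")
        ns, nf, nc, npool, dff, dm, nh = (int(v) for v in tup)
        return cls(in_channels=in_channels, n_classes=n_classes,
                   n_sparse_layers=ns, n_full_layers=nf, n_conv_layers=nc,
                   n_pool_layers=npool, d_ff=dff, d_model=dm, n_heads=nh,
                   **kwargs)


@dataclass(frozen=True)
class TrainConfig:
    """Optimisation settings: adaptive-moment (Adam) minimisation of the
    categorical cross-entropy.  Presets carry the reference per-dataset
    settings — mdd/helsinki: 50 epochs, batch 64, lr 1e-3; pharmaco: 300
    epochs, batch 32, lr 1e-4."""

    epochs: int = 50
    batch_size: int = 64
    learning_rate: float = 1e-3
    optimizer: str = "adam"
    loss: str = "cross_entropy"
    seed: int = 0
    device: str = "cpu"

    def __post_init__(self):
        if self.epochs < 0 or self.batch_size < 1 or self.learning_rate < 0:
            raise ConfigurationError("invalid training configuration")
        if self.optimizer != "adam":
            raise ConfigurationError(f"unknown optimizer {self.optimizer!r}")
        if self.loss != "cross_entropy":
            raise ConfigurationError(f"unknown loss {self.loss!r}")

    @classmethod
    def preset(cls, name: str, **overrides) -> "TrainConfig":
        table = {
            "mdd": dict(epochs=50, batch_size=64, learning_rate=1e-3),
            "helsinki": dict(epochs=50, batch_size=64, learning_rate=1e-3),
            "pharmaco": dict(epochs=300, batch_size=32, learning_rate=1e-4),
        }
        if name not in table:
            raise ConfigurationError(
                f"unknown preset {name!r}; expected one of {sorted(table)}")
        cfg = dict(table[name])
        cfg.update(overrides)
        return cls(**cfg)


# ---------------------------------------------------------------------------
# Encoder stack
# ---------------------------------------------------------------------------

@dataclass
class EncoderStack:
    """The parameterised layer sequence, built deterministically from a
    :class:`ModelConfig` (same config + seed => identical parameters)."""

    config: ModelConfig
    channel_attn: Optional[L.ChannelAttentionParams]
    embed: L.TokenEmbedParams
    blocks: List[L.AttentionBlock]
    distills: List[Optional[L.DistillLayerParams]]
    head: L.PredictHeadParams
    plan: List[Tuple[str, bool]] = field(default_factory=list)

    @classmethod
    def from_config(cls, cfg: ModelConfig) -> "EncoderStack":
        rng = np.random.default_rng(cfg.seed)
        plan = cfg.layer_plan()
        channel_attn = (L.ChannelAttentionParams.init(rng, cfg.in_channels,
                                                      cfg.reduction)
                        if cfg.use_channel_attention else None)
        embed = L.TokenEmbedParams.init(rng, cfg.in_channels, cfg.d_model,
                                        kernel=cfg.conv_kernel,
                                        use_position=cfg.use_position_encoding)
        blocks, distills = [], []
        for _kind, has_distill in plan:
            blocks.append(L.AttentionBlock.init(rng, cfg.d_model, cfg.d_ff,
                                                cfg.n_heads))
            distills.append(
                L.DistillLayerParams.init(rng, cfg.d_model,
                                          conv_kernel=cfg.conv_kernel,
                                          pool_kernel=cfg.pool_kernel,
                                          pool_stride=cfg.pool_stride,
                                          pool_pad=cfg.pool_pad)
                if has_distill else None)
        head = L.PredictHeadParams.init(rng, cfg.d_model, cfg.n_classes)
        return cls(cfg, channel_attn, embed, blocks, distills, head, plan)

    def parameters(self) -> List[Tensor]:
        out: List[Tensor] = []
        if self.channel_attn is not None:
            out += self.channel_attn.params()
        out += self.embed.params()
        for b, d in zip(self.blocks, self.distills):
            out += b.params()
            if d is not None:
                out += d.params()
        out += self.head.params()
        return out

    @property
    def n_parameters(self) -> int:
        return sum(p.data.size for p in self.parameters())


def model_forward(batch: np.ndarray, stack: EncoderStack,
                  train: bool = False, rng=None) -> Tensor:
    """Full forward pass: [N, T, C] epochs -> [N, n_classes] logit Tensor.

    Deterministic given parameters and input (dropout only active when
    ``train`` and an ``rng`` are supplied).
    """
    cfg = stack.config
    batch = np.asarray(batch, dtype=np.float32)
    if batch.ndim != 3:
        raise DataError("batch must be [N, T, C]")
    N, T, C = batch.shape
    if C != cfg.in_channels:
        raise DataError(f"batch has {C} channels, config expects "
                        f"{cfg.in_channels}")
    min_t = cfg.min_input_length()
    if T < min_t:
        raise ConfigurationError(
            f"input length T={T} too short for {cfg.n_pool_layers} distilling "
            f"layers; need T >= {min_t}")
    x = Tensor(batch)
    if stack.channel_attn is not None:
        x = L.channel_attention_batch(x, stack.channel_attn)
    h = L.token_embed_batch(x, stack.embed)
    for (kind, _), block, distill in zip(stack.plan, stack.blocks,
                                         stack.distills):
        h = L.multi_head_batch(h, block, sparse=(kind == "sparse"),
                               c=cfg.query_factor, dropout=cfg.dropout,
                               rng=rng, train=train)
        if distill is not None:
            h = L.distill_batch(h, distill)
    return L.predict_head_batch(h, stack.head)


# ---------------------------------------------------------------------------
# Checkpointing
# ---------------------------------------------------------------------------

def save_checkpoint(stack: EncoderStack, path) -> Path:
    """Serialise parameters + config to a single portable .npz file."""
    path = Path(path)
    arrays = {f"p{i:04d}": p.data for i, p in enumerate(stack.parameters())}
    arrays["config_json"] = np.frombuffer(
        json.dumps(asdict(stack.config)).encode(), dtype=np.uint8)
    np.savez(path, **arrays)
    return path


def load_checkpoint(path) -> EncoderStack:
    path = Path(path)
    with np.load(path) as z:
        cfg_json = bytes(z["config_json"]).decode()
        cfg = ModelConfig(**json.loads(cfg_json))
        stack = EncoderStack.from_config(cfg)
        for i, p in enumerate(stack.parameters()):
            data = z[f"p{i:04d}"]
            if data.shape != p.data.shape:
                raise DataError(f"checkpoint parameter {i} has shape "
                                f"{data.shape}, expected {p.data.shape}")
            p.data = data.astype(np.float32)
    return stack


# ---------------------------------------------------------------------------
# Model / Results objects
# ---------------------------------------------------------------------------

class ConvSparseTransformer:
    """Convolutional sparse transformer classifier bound to an EpochSet.

    Usage mirrors the model/results convention of statistical modelling
    libraries::

        model = ConvSparseTransformer(train_epochs, config=ModelConfig(...))
        res = model.fit(TrainConfig(epochs=10))
        report = res.evaluate(test_epochs)

    The model object holds the data and architecture; :meth:`fit` trains a
    fresh parameter stack and returns a :class:`CSTResults`.
    """

    def __init__(self, data: EpochSet, config: Optional[ModelConfig] = None):
        if config is None:
            config = ModelConfig(in_channels=data.n_channels,
                                 n_classes=data.n_classes)
        if config.in_channels != data.n_channels:
            raise DataError("config.in_channels does not match the data")
        if data.n_classes > config.n_classes or (
                len(data) and data.labels.max() >= config.n_classes):
            raise DataError("labels exceed config.n_classes")
        self.data = data
        self.config = config

    @classmethod
    def from_dataframe(cls, df, fs: float, label_col: str = "label",
                       group_col: Optional[str] = None,
                       config: Optional[ModelConfig] = None):
        """Build from a long-format DataFrame with one row per (epoch, time)
        and channel columns; mostly a convenience for small examples."""
        import pandas as pd  # noqa: F401

        chans = [c for c in df.columns
                 if c not in {label_col, group_col, "epoch", "time"}]
        n = df["epoch"].nunique()
        epochs = np.stack([
            df[df["epoch"] == e][chans].to_numpy() for e in range(n)])
        labels = np.array([
            df[df["epoch"] == e][label_col].iloc[0] for e in range(n)])
        groups = ([df[df["epoch"] == e][group_col].iloc[0] for e in range(n)]
                  if group_col else [""] * n)
        names = [str(c) for c in sorted(set(labels))]
        es = EpochSet(epochs, labels, fs, names, groups)
        return cls(es, config=config)

    def fit(self, train_config: Optional[TrainConfig] = None,
            verbose: bool = False) -> "CSTResults":
        """Train with Adam on categorical cross-entropy; returns results.

        Fully reproducible: parameter initialisation comes from
        ``config.seed``, batch order and dropout from ``train_config.seed``.
        """
        tc = train_config or TrainConfig()
        stack = EncoderStack.from_config(self.config)
        opt = Adam(stack.parameters(), lr=tc.learning_rate)
        rng = np.random.default_rng(tc.seed)
        X, y = self.data.epochs, self.data.labels
        n = len(self.data)
        history = []
        for epoch in range(tc.epochs):
            order = rng.permutation(n)
            losses = []
            for start in range(0, n, tc.batch_size):
                idx = order[start:start + tc.batch_size]
                logits = model_forward(X[idx], stack, train=True, rng=rng)
                loss = cross_entropy(logits, y[idx])
                if not np.isfinite(loss.data):
                    raise TrainingDivergedError(
                        f"non-finite loss at epoch {epoch}, batch "
                        f"{start // tc.batch_size}: {float(loss.data)!r} "
                        f"(lr={tc.learning_rate}, batch={tc.batch_size})")
                opt.zero_grad()
                loss.backward()
                opt.step()
                losses.append(float(loss.data))
            history.append(float(np.mean(losses)) if losses else float("nan"))
            if verbose:
                print(f"epoch {epoch + 1}/{tc.epochs}  loss {history[-1]:.4f}")
        return CSTResults(self, stack, tc, history)


class CSTResults:
    """Fitted-model results: parameters, loss history, prediction,
    evaluation and a text summary."""

    def __init__(self, model: ConvSparseTransformer, stack: EncoderStack,
                 train_config: TrainConfig, loss_history: List[float]):
        self.model = model
        self.stack = stack
        self.train_config = train_config
        self.loss_history = list(loss_history)

    # -- inference ----------------------------------------------------------
    def predict_logits(self, data, batch_size: int = 128) -> np.ndarray:
        X = data.epochs if isinstance(data, EpochSet) else np.asarray(data)
        outs = []
        for start in range(0, len(X), batch_size):
            outs.append(model_forward(X[start:start + batch_size],
                                      self.stack).data)
        return np.concatenate(outs) if outs else np.empty(
            (0, self.model.config.n_classes))

    def predict_proba(self, data) -> np.ndarray:
        z = self.predict_logits(data)
        z = z - z.max(axis=1, keepdims=True)
        e = np.exp(z)
        return e / e.sum(axis=1, keepdims=True)

    def predict(self, data) -> np.ndarray:
        return self.predict_logits(data).argmax(axis=1)

    def evaluate(self, data: EpochSet):
        from .metrics import compute_metrics
        return compute_metrics(data.labels, self.predict_proba(data),
                               class_names=list(data.class_names))

    # -- reporting ----------------------------------------------------------
    def summary(self) -> str:
        cfg = self.model.config
        buf = _io.StringIO()
        w = buf.write
        w("Convolutional Sparse Transformer — fit summary\n")
        w("=" * 52 + "\n")
        w(f"epochs (data)        : {len(self.model.data)}\n")
        w(f"epoch shape [T x C]  : {self.model.data.n_times} x "
          f"{self.model.data.n_channels}\n")
        w(f"classes              : {list(self.model.data.class_names)}\n")
        w(f"attention layers     : {cfg.n_sparse_layers} sparse + "
          f"{cfg.n_full_layers} full ({cfg.n_heads} heads)\n")
        w(f"d_model / d_ff       : {cfg.d_model} / {cfg.d_ff}\n")
        w(f"distilling layers    : "
          f"{cfg.n_pool_layers if cfg.use_distillation else 0}\n")
        w(f"channel attention    : {cfg.use_channel_attention}\n")
        w(f"sparse attention     : {cfg.use_sparse_attention} "
          f"(query factor {cfg.query_factor})\n")
        w(f"parameters           : {self.stack.n_parameters}\n")
        w(f"training             : {self.train_config.epochs} epochs, batch "
          f"{self.train_config.batch_size}, lr "
          f"{self.train_config.learning_rate}\n")
        if self.loss_history:
            w(f"loss first -> last   : {self.loss_history[0]:.4f} -> "
              f"{self.loss_history[-1]:.4f}\n")
        return buf.getvalue()

    def save(self, path) -> Path:
        return save_checkpoint(self.stack, path)

    def plot_loss(self, ax=None):
        """Training-loss curve (matplotlib axis)."""
        import matplotlib
        matplotlib.use("Agg", force=False)
        import matplotlib.pyplot as plt

        if ax is None:
            _fig, ax = plt.subplots()
        ax.plot(np.arange(1, len(self.loss_history) + 1), self.loss_history,
                marker="o")
        ax.set_xlabel("training epoch")
        ax.set_ylabel("mean cross-entropy")
        return ax
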