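"""Evaluation protocols: repeated stratified holdout, k-fold cross-
validation, the three-axis ablation switchboard, and the hyperparameter
sensitivity sweep.

Every protocol trains a fresh model per split and aggregates fold-level
metric reports as mean +/- standard deviation (sample sd, n-1 denominator).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd

from .exceptions import ConfigurationError, ParameterError
from .io import EpochSet, kfold, split_holdout
from .metrics import MetricsReport
from .model import ConvSparseTransformer, ModelConfig, TrainConfig

__all__ = ["CVResult", "run_holdout_repeats", "run_cv", "run_ablation",
           "run_sensitivity", "ABLATION_GRID"]

_METRICS = ("accuracy", "precision", "recall", "f1", "roc_auc")


@dataclass
class CVResult:
    """Per-fold metric reports plus mean +/- sd aggregation."""

    folds: List[MetricsReport]
    protocol: str = ""

    def aggregate(self) -> Dict[str, Tuple[float, float]]:
        out = {}
        for m in _METRICS:
            vals = [r.to_dict()[m] for r in self.folds]
            vals = [v for v in vals if np.isfinite(v)]
            if not vals:
                out[m] = (float("nan"), float("nan"))
                continue
            mean = float(np.mean(vals))
            sd = float(np.std(vals, ddof=1)) if len(vals) > 1 else 0.0
            out[m] = (mean, sd)
        return out

    def mean(self, metric: str) -> float:
        return self.aggregate()[metric][0]

    def to_frame(self) -> pd.DataFrame:
        rows = [r.to_dict() for r in self.folds]
        return pd.DataFrame(rows, index=[f"fold{i}" for i in range(len(rows))])

    def summary(self) -> str:
        lines = [f"protocol: {self.protocol} ({len(self.folds)} folds)"]
        for m, (mu, sd) in self.aggregate().items():
            lines.append(f"  {m:<10} {mu:.3f} ± {sd:.3f}")
        return "\n".join(lines)


def _child_seeds(seed: int, n: int) -> List[int]:
    """n reproducible sub-seeds below 2**31."""
    ss = np.random.SeedSequence(seed)
    return [int(s) for s in ss.generate_state(n) % (2 ** 31)]


def _fit_and_score(train: EpochSet, test: EpochSet, model_cfg: ModelConfig,
                   train_cfg: TrainConfig) -> MetricsReport:
    model = ConvSparseTransformer(train, config=model_cfg)
    res = model.fit(train_cfg)
    return res.evaluate(test)


def run_holdout_repeats(es: EpochSet, model_cfg: ModelConfig,
                        train_cfg: TrainConfig, n_repeats: int = 10,
                        seed: int = 0, train_frac: float = 0.7) -> CVResult:
    """``n_repeats`` independent stratified holdout splits (default 7:3),
    a fresh model per repeat, aggregated mean +/- sd."""
    if n_repeats < 1:
        raise ParameterError("n_repeats must be >= 1")
    seeds = _child_seeds(seed, 2 * n_repeats)
    reports = []
    for r in range(n_repeats):
        train, test = split_holdout(es, train_frac, seed=seeds[2 * r])
        mc = replace(model_cfg, seed=seeds[2 * r + 1])
        tc = replace(train_cfg, seed=seeds[2 * r + 1])
        reports.append(_fit_and_score(train, test, mc, tc))
    return CVResult(reports, protocol=f"holdout x{n_repeats} "
                                      f"({train_frac:.0%} train)")


def run_cv(es: EpochSet, k: int, model_cfg: ModelConfig,
           train_cfg: TrainConfig, seed: int = 0,
           grouped: bool = False) -> CVResult:
    """k-fold cross-validation; every epoch is tested exactly once.

    ``grouped=True`` keeps all epochs of a subject in one fold (the
    leakage-safe option when several epochs come from the same recording).
    """
    folds = kfold(es, k, seed=seed, grouped=grouped)
    seeds = _child_seeds(seed, k)
    reports = []
    for i, (tr, te) in enumerate(folds):
        mc = replace(model_cfg, seed=seeds[i])
        tc = replace(train_cfg, seed=seeds[i])
        reports.append(_fit_and_score(es.subset(tr), es.subset(te), mc, tc))
    return CVResult(reports, protocol=f"{k}-fold cv"
                                      + (" (grouped)" if grouped else ""))


# the standard ablation grid: (channel attention, sparse attention,
# distillation) — full model plus each single ablation
ABLATION_GRID: Tuple[Tuple[bool, bool, bool], ...] = (
    (True, True, True),
    (False, True, True),
    (True, False, True),
    (True, True, False),
)


def run_ablation(es: EpochSet, base_cfg: ModelConfig,
                 train_cfg: TrainConfig, seed: int = 0,
                 train_frac: float = 0.7) -> pd.DataFrame:
    """Evaluate the four-row ablation switchboard on one stratified split.

    Rows toggle (channel attention, sparse attention, distillation);
    sparse off means dense attention in every layer, distillation off
    removes all convolution/pooling so temporal length is preserved.
    The same split and seeds are used for every row, so differences are
    attributable to the architecture flags alone.
    """
    train, test = split_holdout(es, train_frac, seed=seed)
    rows = []
    for ca, sa, di in ABLATION_GRID:
        cfg = replace(base_cfg, use_channel_attention=ca,
                      use_sparse_attention=sa, use_distillation=di, seed=seed)
        report = _fit_and_score(train, test, cfg, replace(train_cfg, seed=seed))
        row = {"channel_attention": ca, "sparse_attention": sa,
               "distillation": di}
        row.update(report.to_dict())
        rows.append(row)
    return pd.DataFrame(rows)


def run_sensitivity(es: EpochSet, grid: Sequence[Sequence[float]],
                    train_cfg: TrainConfig, seed: int = 0, k: int = 5,
                    base_cfg: Optional[ModelConfig] = None) -> pd.DataFrame:
    """Hyperparameter sensitivity sweep over 7-tuples
    [n_sparse, n_full, n_conv, n_pool, d_ff, d_model, n_heads].

    Each valid tuple is scored by ``k``-fold cross-validation; invalid
    tuples (inconsistent geometry, input too short for the pooling stack)
    become error rows rather than crashes.
    """
    rows = []
    for tup in grid:
        row: Dict[str, object] = {"hyperparameters": list(tup)}
        try:
            kwargs = {}
            if base_cfg is not None:
                kwargs = dict(query_factor=base_cfg.query_factor,
                              dropout=base_cfg.dropout,
                              use_position_encoding=base_cfg.use_position_encoding)
            cfg = ModelConfig.from_tuple(tup, in_channels=es.n_channels,
                                         n_classes=es.n_classes, **kwargs)
            if es.n_times < cfg.min_input_length():
                raise ConfigurationError(
                    f"T={es.n_times} too short for {cfg.n_pool_layers} "
                    f"pooling layers (need T >= {cfg.min_input_length()})")
            result = run_cv(es, k, cfg, train_cfg, seed=seed)
            row["status"] = "ok"
            for m, (mu, sd) in result.aggregate().items():
                row[f"{m}_mean"] = mu
                row[f"{m}_sd"] = sd
        except ConfigurationError as e:
            row["status"] = f"configuration error: {e}"
        rows.append(row)
    return pd.DataFrame(rows)
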