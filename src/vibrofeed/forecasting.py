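"""Sequence forecasting of feeding intensity 5 s ahead.

Supervised windows pair a 5-s (50-step) context of per-step feature vectors
``[s_i, t_i, S, D, V, Φ]`` with either the summed displacement of the next
5-s window (scalar mode) or the next 50 per-sample sums (trajectory mode).
Features and targets are z-scored with statistics fitted on the training
split only; metrics are always reported on the de-normalized μm scale.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from . import nn
from .signal_processing import (
    FilterConfig,
    TriaxialTrace,
    ZScoreStats,
    triaxial_sum,
    zscore_fit,
)

__all__ = [
    "SupervisedData",
    "ModelConfig",
    "TrainConfig",
    "Metrics",
    "ForecastModel",
    "trial_features",
    "build_supervised",
    "train_forecaster",
    "predict",
    "evaluate",
    "metrics_from_predictions",
    "compare_architectures",
]

log = logging.getLogger(__name__)

CONTEXT_LEN = 50
HORIZON = 50
N_FEATURES = 6


class TrainingDivergedError(RuntimeError):
    """Raised when the loss turns non-finite during training."""


@dataclass
class SupervisedData:
    """Stacked supervised samples from a set of trials."""

    x: np.ndarray  # (N, context_len, 6) raw-scale features
    y: np.ndarray  # (N,) scalar mode or (N, 50) trajectory mode
    trial_index: np.ndarray  # (N,) source-trial id for by-trial splits
    mode: str  # "scalar" | "trajectory"
    context_len: int = CONTEXT_LEN

    def __len__(self) -> int:
        return len(self.x)


@dataclass
class ModelConfig:
    arch: str = "lstm"  # lstm | gru | transformer
    hidden: int = 128
    n_layers: int = 2
    dropout: float = 0.2
    dense: int = 64
    d_ff: int = 256
    output_dim: int = 1  # 1 (scalar) or 50 (trajectory)

    def __post_init__(self) -> None:
        if self.output_dim not in (1, HORIZON):
            raise ValueError("output dimension must be 1 or 50")


@dataclass
class TrainConfig:
    learning_rate: float = 0.001
    batch_size: int = 32
    max_epochs: int = 200
    patience: int = 20
    val_fraction: float = 0.2
    split_by: str = "sample"  # "sample" (default) or "trial"
    seed: int = 0
    max_train_samples: int | None = None  # optional desk-scale cap

    def __post_init__(self) -> None:
        if not (0 < self.val_fraction < 1):
            raise ValueError("validation fraction must be in (0, 1)")


@dataclass(frozen=True)
class Metrics:
    rmse: float
    mae: float
    r_squared: float

    def __post_init__(self) -> None:
        if self.rmse < self.mae - 1e-9:
            raise ValueError("RMSE cannot be below MAE")


@dataclass
class ForecastModel:
    """Trained sequence regressor plus its normalization statistics."""

    net: object
    model_cfg: ModelConfig
    train_cfg: TrainConfig
    x_stats: ZScoreStats
    y_stats: ZScoreStats
    history: dict = field(default_factory=dict)
    val_metrics: Metrics | None = None
    train_indices: np.ndarray | None = None
    val_indices: np.ndarray | None = None


def trial_features(trace: TriaxialTrace, gate_um: float = 0.5) -> np.ndarray:
    """Per-step feature matrix [s_i, t_i, S, D, V, Φ] for one trial."""
    cfg = trace.meta
    if cfg is None:
        raise ValueError("trace has no trial configuration metadata")
    s = triaxial_sum(trace, FilterConfig(gate_um))
    n = len(s)
    feats = np.empty((n, N_FEATURES), dtype=np.float64)
    feats[:, 0] = s
    feats[:, 1] = trace.timestamps
    feats[:, 2] = cfg.size_g
    feats[:, 3] = cfg.density
    feats[:, 4] = cfg.feed_rate
    feats[:, 5] = cfg.pellet_mm
    return feats


def build_supervised(
    trials: list[TriaxialTrace],
    context_len: int = CONTEXT_LEN,
    stride: int = 1,
    mode: str = "scalar",
    gate_um: float = 0.5,
) -> SupervisedData:
    """Slide context/target windows over each trial at the given stride.

    Trials shorter than ``context_len + 50`` samples are skipped with a
    warning.  Targets stay on the raw μm scale; normalization statistics are
    fitted later, on the training split only (see :func:`train_forecaster`).
    """
    if mode not in ("scalar", "trajectory"):
        raise ValueError("mode must be 'scalar' or 'trajectory'")
    xs, ys, idxs = [], [], []
    for ti, trace in enumerate(trials):
        feats = trial_features(trace, gate_um)
        n = len(feats)
        if n < context_len + HORIZON:
            warnings.warn(f"trial {ti} too short for one supervised sample; skipped",
                          stacklevel=2)
            continue
        starts = np.arange(0, n - context_len - HORIZON + 1, stride)
        s_col = feats[:, 0]
        for st in starts:
            xs.append(feats[st : st + context_len])
            future = s_col[st + context_len : st + context_len + HORIZON]
            ys.append(future.sum() if mode == "scalar" else future)
            idxs.append(ti)
    if not xs:
        raise ValueError("no supervised samples could be built")
    return SupervisedData(
        x=np.asarray(xs, dtype=np.float32), y=np.asarray(ys),
        trial_index=np.asarray(idxs), mode=mode, context_len=context_len,
    )


def _split_indices(data: SupervisedData, cfg: TrainConfig) -> tuple[np.ndarray, np.ndarray]:
    rng = np.random.default_rng(cfg.seed)
    n = len(data)
    if cfg.split_by == "trial":
        trials = np.unique(data.trial_index)
        rng.shuffle(trials)
        n_val = max(1, int(round(cfg.val_fraction * len(trials))))
        val_trials = set(trials[:n_val].tolist())
        val_mask = np.isin(data.trial_index, list(val_trials))
        return np.nonzero(~val_mask)[0], np.nonzero(val_mask)[0]
    perm = rng.permutation(n)
    n_val = max(1, int(round(cfg.val_fraction * n)))
    return perm[n_val:], perm[:n_val]


def _normalize(data: SupervisedData, train_idx: np.ndarray):
    flat = data.x[train_idx].reshape(-1, data.x.shape[-1])
    # constant static features across a homogeneous training set would have
    # zero spread; give them unit sd instead of failing
    mean = flat.mean(axis=0)
    sd = flat.std(axis=0, ddof=1)
    sd[sd <= 0] = 1.0
    x_stats = ZScoreStats(mean, sd)
    y_train = data.y[train_idx].reshape(len(train_idx), -1)
    y_stats = zscore_fit(y_train.reshape(-1, 1))
    return x_stats, y_stats


def _forward_in_batches(net, x_norm: np.ndarray, batch: int = 256) -> np.ndarray:
    outs = []
    for i in range(0, len(x_norm), batch):
        t = nn.Tensor(x_norm[i : i + batch])
        outs.append(net.forward(t, rng=None).data)
    return np.concatenate(outs, axis=0)


def train_forecaster(
    data: SupervisedData,
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> ForecastModel:
    """Train a forecaster with Adam/MSE and early stopping on validation loss.

    The data is split 80/20 (by sample by default), normalization statistics
    are fitted on the training split only, and the best-validation weights
    are restored when the patience budget is exhausted.  Deterministic for a
    fixed seed.
    """
    model_cfg = model_cfg if model_cfg is not None else ModelConfig()
    train_cfg = train_cfg if train_cfg is not None else TrainConfig()
    if (data.mode == "scalar") != (model_cfg.output_dim == 1):
        raise ValueError("model output dimension does not match data mode")

    train_idx, val_idx = _split_indices(data, train_cfg)
    if train_cfg.max_train_samples is not None and len(train_idx) > train_cfg.max_train_samples:
        sub_rng = np.random.default_rng(train_cfg.seed + 1)
        train_idx = sub_rng.choice(train_idx, train_cfg.max_train_samples, replace=False)
    x_stats, y_stats = _normalize(data, train_idx)

    def norm_x(x):
        return ((x - x_stats.mean) / x_stats.sd).astype(nn.DTYPE)

    def norm_y(y):
        return ((y.reshape(len(y), -1) - y_stats.mean) / y_stats.sd).astype(nn.DTYPE)

    x_train, y_train = norm_x(data.x[train_idx]), norm_y(data.y[train_idx])
    x_val, y_val = norm_x(data.x[val_idx]), norm_y(data.y[val_idx])
    if len(x_train) < 2 * train_cfg.batch_size:
        raise ValueError("need at least two batches of training data")

    rng = np.random.default_rng(train_cfg.seed)
    net = nn.build_net(
        model_cfg.arch, rng, N_FEATURES, data.context_len, model_cfg.output_dim,
        hidden=model_cfg.hidden, dropout=model_cfg.dropout, dense=model_cfg.dense,
        d_ff=model_cfg.d_ff, n_layers=model_cfg.n_layers,
    )
    opt = nn.Adam(net.parameters(), lr=train_cfg.learning_rate)
    history = {"train_loss": [], "val_loss": []}
    best_val = np.inf
    best_snapshot = opt.state_snapshot()
    since_best = 0

    for epoch in range(train_cfg.max_epochs):
        perm = rng.permutation(len(x_train))
        total, count = 0.0, 0
        for i in range(0, len(perm) - train_cfg.batch_size + 1, train_cfg.batch_size):
            idx = perm[i : i + train_cfg.batch_size]
            xb = nn.Tensor(x_train[idx])
            yb = nn.Tensor(y_train[idx])
            pred = net.forward(xb, rng=rng)
            err = pred - yb
            loss = (err * err).mean()
            if not np.isfinite(loss.data):
                raise TrainingDivergedError(
                    f"non-finite loss at epoch {epoch}: {float(loss.data)}"
                )
            opt.zero_grad()
            loss.backward()
            opt.step()
            total += float(loss.data)
            count += 1
        train_loss = total / max(count, 1)
        val_pred = _forward_in_batches(net, x_val)
        val_loss = float(np.mean((val_pred - y_val) ** 2))
        history["train_loss"].append(train_loss)
        history["val_loss"].append(val_loss)
        log.info("epoch %d train_mse %.5f val_mse %.5f", epoch, train_loss, val_loss)
        if val_loss < best_val - 1e-12:
            best_val = val_loss
            best_snapshot = opt.state_snapshot()
            since_best = 0
        else:
            since_best += 1
            if since_best >= train_cfg.patience:
                log.info("early stop at epoch %d (best val %.5f)", epoch, best_val)
                break
    opt.restore(best_snapshot)

    model = ForecastModel(net, model_cfg, train_cfg, x_stats, y_stats, history,
                          train_indices=train_idx, val_indices=val_idx)
    model.val_metrics = evaluate(model, data.x[val_idx], data.y[val_idx])
    return model


def predict(model: ForecastModel, context: np.ndarray) -> np.ndarray:
    """De-normalized μm forecast for one context or a batch of contexts."""
    x = np.asarray(context, dtype=float)
    single = x.ndim == 2
    if single:
        x = x[None]
    if x.ndim != 3 or x.shape[-1] != N_FEATURES:
        raise ValueError(
            f"context must be (n, context_len, {N_FEATURES}); got {x.shape}"
        )
    xn = ((x - model.x_stats.mean) / model.x_stats.sd).astype(nn.DTYPE)
    out = _forward_in_batches(model.net, xn)
    out = out * model.y_stats.sd + model.y_stats.mean
    if model.model_cfg.output_dim == 1:
        out = out[:, 0]
    return out[0] if single else out


def metrics_from_predictions(y_true: np.ndarray, y_pred: np.ndarray) -> Metrics:
    """RMSE / MAE / R² of paired predictions (μm scale)."""
    truth = np.asarray(y_true, dtype=float).reshape(len(y_true), -1)
    pred = np.asarray(y_pred, dtype=float).reshape(truth.shape)
    err = pred - truth
    ss_tot = float(((truth - truth.mean()) ** 2).sum())
    if ss_tot == 0:
        raise ValueError("zero target variance: R² undefined")
    rmse = float(np.sqrt(np.mean(err**2)))
    mae = float(np.mean(np.abs(err)))
    r2 = 1.0 - float((err**2).sum()) / ss_tot
    return Metrics(rmse, mae, r2)


def evaluate(model: ForecastModel, x: np.ndarray, y: np.ndarray) -> Metrics:
    """RMSE / MAE / R² of a model on an evaluation set (de-normalized μm)."""
    if len(x) == 0:
        raise ValueError("empty evaluation set")
    pred = np.asarray(predict(model, x), dtype=float)
    return metrics_from_predictions(y, pred)


def compare_architectures(
    data: SupervisedData,
    seeds: list[int],
    model_cfg: ModelConfig | None = None,
    train_cfg: TrainConfig | None = None,
) -> "pd.DataFrame":
    """Train LSTM/GRU/Transformer on identical splits; one metrics row each.

    The empirical ordering is recorded, not asserted: results on synthetic
    data need not reproduce orderings observed on live-fish signals.
    """
    import pandas as pd

    base_model = model_cfg if model_cfg is not None else ModelConfig()
    base_train = train_cfg if train_cfg is not None else TrainConfig()
    rows = []
    for seed in seeds:
        for arch in ("lstm", "gru", "transformer"):
            mcfg = ModelConfig(**{**base_model.__dict__, "arch": arch})
            tcfg = TrainConfig(**{**base_train.__dict__, "seed": seed})
            model = train_forecaster(data, mcfg, tcfg)
            m = model.val_metrics
            rows.append(
                {"arch": arch, "seed": seed, "rmse_um": m.rmse, "mae_um": m.mae,
                 "r2": m.r_squared}
            )
    return pd.DataFrame(rows)
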