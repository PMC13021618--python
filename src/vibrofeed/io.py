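"""Flat-file I/O: trace CSVs, dataset manifests, model artifacts, run configs.

All interchange formats are plain CSV/JSON/YAML (no community standard exists
for surface-vibration traces); trained-model weights are stored as a
compressed npz next to a JSON sidecar describing the architecture, training
configuration and normalization statistics.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import nn
from .forecasting import ForecastModel, Metrics, ModelConfig, TrainConfig
from .signal_processing import SAMPLING_RATE_HZ, TriaxialTrace, ZScoreStats
from .synthetic import TrialConfig

__all__ = [
    "TraceParseError",
    "read_trace",
    "write_trace",
    "read_manifest",
    "write_manifest",
    "save_model",
    "load_model",
    "load_run_config",
]

TRACE_COLUMNS = ["t", "x_um", "y_um", "z_um"]


class TraceParseError(ValueError):
    """Raised for malformed trace files, with the offending line when known."""


def write_trace(trace: TriaxialTrace, path: str | Path) -> None:
    df = pd.DataFrame(
        {"t": trace.timestamps, "x_um": trace.x, "y_um": trace.y, "z_um": trace.z}
    )
    df.to_csv(path, index=False, float_format="%.9g")


def read_trace(path: str | Path, meta: TrialConfig | None = None) -> TriaxialTrace:
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise TraceParseError(f"{path}: empty trace file") from exc
    missing = [c for c in TRACE_COLUMNS if c not in df.columns]
    if missing:
        raise TraceParseError(f"{path}: missing columns {missing}")
    if len(df) == 0:
        raise TraceParseError(f"{path}: no samples")
    for col in TRACE_COLUMNS:
        bad = df.index[~np.isfinite(pd.to_numeric(df[col], errors="coerce"))]
        if len(bad):
            # +2: header line plus 1-based numbering
            raise TraceParseError(f"{path}: malformed value in line {bad[0] + 2}")
    t = df["t"].to_numpy(dtype=float)
    if len(t) > 1:
        nonmono = np.nonzero(np.diff(t) <= 0)[0]
        if nonmono.size:
            raise TraceParseError(
                f"{path}: non-monotone time at line {nonmono[0] + 3}"
            )
    return TriaxialTrace(
        timestamps=t,
        x=df["x_um"].to_numpy(dtype=float),
        y=df["y_um"].to_numpy(dtype=float),
        z=df["z_um"].to_numpy(dtype=float),
        fs=1.0 / float(np.median(np.diff(t))) if len(t) > 1 else SAMPLING_RATE_HZ,
        meta=meta,
    )


def write_manifest(manifest: pd.DataFrame, path: str | Path) -> None:
    manifest.to_csv(path, index=False)


def read_manifest(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


# ---------------------------------------------------------------------------
# model artifacts


def save_model(model: ForecastModel, directory: str | Path) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    params = model.net.parameters()
    np.savez_compressed(
        directory / "weights.npz",
        **{f"p{i}": p.data for i, p in enumerate(params)},
    )
    sidecar = {
        "model_cfg": dataclasses.asdict(model.model_cfg),
        "train_cfg": dataclasses.asdict(model.train_cfg),
        "x_stats": {"mean": model.x_stats.mean.tolist(), "sd": model.x_stats.sd.tolist()},
        "y_stats": {"mean": model.y_stats.mean.tolist(), "sd": model.y_stats.sd.tolist()},
        "history": {k: [float(v) for v in vs] for k, vs in model.history.items()},
        "val_metrics": dataclasses.asdict(model.val_metrics) if model.val_metrics else None,
        "context_len": 50,
        "zscore_convention": "sample (ddof=1)",
    }
    (directory / "model.json").write_text(json.dumps(sidecar, indent=2))


def load_model(directory: str | Path) -> ForecastModel:
    directory = Path(directory)
    sidecar = json.loads((directory / "model.json").read_text())
    model_cfg = ModelConfig(**sidecar["model_cfg"])
    train_cfg = TrainConfig(**sidecar["train_cfg"])
    rng = np.random.default_rng(train_cfg.seed)
    net = nn.build_net(
        model_cfg.arch, rng, 6, sidecar["context_len"], model_cfg.output_dim,
        hidden=model_cfg.hidden, dropout=model_cfg.dropout, dense=model_cfg.dense,
        d_ff=model_cfg.d_ff, n_layers=model_cfg.n_layers,
    )
    with np.load(directory / "weights.npz") as npz:
        for i, p in enumerate(net.parameters()):
            p.data = npz[f"p{i}"].astype(nn.DTYPE)
    x_stats = ZScoreStats(
        np.asarray(sidecar["x_stats"]["mean"]), np.asarray(sidecar["x_stats"]["sd"])
    )
    y_stats = ZScoreStats(
        np.asarray(sidecar["y_stats"]["mean"]), np.asarray(sidecar["y_stats"]["sd"])
    )
    model = ForecastModel(net, model_cfg, train_cfg, x_stats, y_stats,
                          sidecar.get("history", {}))
    if sidecar.get("val_metrics"):
        model.val_metrics = Metrics(**sidecar["val_metrics"])
    return model


def load_run_config(path: str | Path) -> dict:
    """Load a flat YAML run configuration (missing file -> empty dict)."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError(f"{path}: run config must be a mapping")
    return cfg
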