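"""Predictive stop-feeding controller and closed-loop simulation harness.

The controller mirrors the deployed decision rule: a rolling 50-sample buffer
of per-sample triaxial sums feeds a trajectory forecaster every 5 s; a
predicted trajectory whose second-half mean falls below 0.9x its first-half
mean counts as a decline, and two consecutive declines stop the feeder.

Because no live fish are available, sessions run against a synthetic tank
with capacity-based satiation: appetite decays linearly with consumed feed
and scales the vibration signal, so the controller's inputs weaken as the
fish approach satiation.  Sessions are scored by residual feed rate
(uneaten / delivered x 100%).
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .forecasting import ForecastModel, predict, HORIZON, N_FEATURES
from .signal_processing import FilterConfig, amplitude_filter
from .synthetic import GeneratorParams, TrialConfig, generate_trial_parts

__all__ = [
    "ControllerConfig",
    "ControllerState",
    "TankModel",
    "SessionResult",
    "detect_decline",
    "controller_step",
    "proportional_output",
    "rfr",
    "tank_step",
    "simulate_session",
]


@dataclass
class ControllerConfig:
    initial_speed_gps: float = 2.0
    buffer_len: int = 50
    decision_period_s: float = 5.0
    decline_ratio: float = 0.9
    decline_stop_count: int = 2
    loop_dt_s: float = 0.1
    output_scale: int = 255

    def __post_init__(self) -> None:
        if not (0 < self.decline_ratio < 1):
            raise ValueError("decline ratio must be in (0, 1)")
        if self.decline_stop_count < 1:
            raise ValueError("decline stop count must be >= 1")


@dataclass
class ControllerState:
    buffer: np.ndarray
    decline_count: int = 0
    feeder_speed_gps: float = 2.0
    stopped: bool = False

    @classmethod
    def fresh(cls, cfg: ControllerConfig) -> "ControllerState":
        return cls(buffer=np.zeros(cfg.buffer_len), feeder_speed_gps=cfg.initial_speed_gps)

    def push_sample(self, s_um: float) -> None:
        self.buffer = np.roll(self.buffer, -1)
        self.buffer[-1] = s_um


@dataclass
class TankModel:
    """Capacity-based satiation surrogate for a stocked tank.

    Capacity defaults to 1% of total biomass; hungry fish can clear feed
    faster than the feeder delivers it, so uneaten feed only accumulates
    once appetite has sagged.  ``appetite`` decays linearly from 1 to 0 as
    the capacity fills and multiplies the feeding-vibration envelope.
    """

    size_g: float = 300.0
    density: float = 30.0
    capacity_factor: float = 0.015  # fraction of body mass per fish
    intake_factor_gps: float = 0.5  # per-fish max intake scaling (g/s)
    consumed_g: float = 0.0
    pending_g: float = 0.0

    @property
    def satiation_capacity_g(self) -> float:
        return self.capacity_factor * self.size_g * self.density

    @property
    def max_intake_rate_gps(self) -> float:
        return self.intake_factor_gps * self.density

    @property
    def appetite(self) -> float:
        return max(0.0, 1.0 - self.consumed_g / self.satiation_capacity_g)


def detect_decline(prediction: np.ndarray, ratio: float = 0.9) -> bool:
    """True iff the second-half mean falls strictly below ratio x first-half mean."""
    pred = np.asarray(prediction, dtype=float)
    if pred.shape != (HORIZON,):
        raise ValueError(f"prediction must have exactly {HORIZON} values")
    first = float(pred[:25].mean())
    second = float(pred[25:].mean())
    return second < ratio * first


def controller_step(
    state: ControllerState,
    prediction: np.ndarray | None,
    cfg: ControllerConfig,
) -> tuple[ControllerState, str]:
    """Advance the decision logic one cycle; returns (state, command).

    ``prediction`` is supplied only at 5-s decision boundaries; between them
    the command is simply the current mode.  A decline increments the
    counter, any non-decline resets it, and reaching the stop count latches
    the stopped flag.
    """
    if state.stopped:
        warnings.warn("controller already stopped; step is a no-op", stacklevel=2)
        return state, "stop"
    if prediction is None:
        return state, "maintain"
    if detect_decline(prediction, cfg.decline_ratio):
        state.decline_count += 1
    else:
        state.decline_count = 0
    if state.decline_count >= cfg.decline_stop_count:
        state.stopped = True
        state.feeder_speed_gps = 0.0
        return state, "stop"
    return state, "maintain"


def proportional_output(predicted_sum_um: float, session_max_um: float,
                        scale: int = 255) -> int:
    """Map a window-sum forecast onto a 0..scale feeder drive signal."""
    if session_max_um <= 0:
        raise ValueError("session maximum must be positive")
    frac = min(max(predicted_sum_um / session_max_um, 0.0), 1.0)
    return int(math.floor(scale * frac + 0.5))  # round half up


def rfr(residual_mass_g: float, total_mass_g: float) -> float:
    """Residual feed rate: uneaten mass as a percentage of delivered mass."""
    if total_mass_g <= 0:
        raise ValueError("total feed mass must be positive")
    if residual_mass_g < 0:
        raise ValueError("residual mass cannot be negative")
    return 100.0 * residual_mass_g / total_mass_g


def tank_step(tank: TankModel, delivered_g: float, dt_s: float) -> float:
    """Deliver feed for one step and let the fish eat; returns mass eaten."""
    if dt_s <= 0:
        raise ValueError("dt must be positive")
    tank.pending_g += delivered_g
    eaten = min(tank.pending_g, tank.max_intake_rate_gps * tank.appetite * dt_s)
    tank.consumed_g += eaten
    tank.pending_g -= eaten
    return eaten


@dataclass
class SessionResult:
    total_fed_g: float
    residual_g: float
    rfr_pct: float
    stop_time_s: float | None
    consumed_g: float
    appetite_at_stop: float | None
    seed: int
    command_log: pd.DataFrame = field(repr=False, default=None)


def simulate_session(
    config: TrialConfig,
    ctrl_cfg: ControllerConfig,
    model: ForecastModel,
    seed: int,
    tank: TankModel | None = None,
    params: GeneratorParams | None = None,
    max_session_s: float = 120.0,
) -> SessionResult:
    """Run one closed-loop feeding session at 10 Hz.

    Each step the synthetic feeding signal (scaled by current appetite) is
    gated, summed and pushed into the rolling buffer; at every whole 5-s
    boundary the trajectory forecaster predicts the next 50 per-sample sums
    and the Table-style stop logic decides whether to keep feeding.
    Deterministic for a fixed seed.
    """
    if model.model_cfg.output_dim != HORIZON:
        raise ValueError("closed-loop control needs a trajectory-mode forecaster")
    p = params if params is not None else GeneratorParams()
    dt = ctrl_cfg.loop_dt_s
    decision_steps = int(round(ctrl_cfg.decision_period_s / dt))
    if decision_steps != ctrl_cfg.buffer_len:
        raise ValueError("decision period and buffer length disagree at 10 Hz")
    tank = tank if tank is not None else TankModel(size_g=config.size_g,
                                                  density=config.density)
    sess_cfg = TrialConfig(
        size_g=config.size_g, density=config.density,
        feed_rate=ctrl_cfg.initial_speed_gps, pellet_mm=config.pellet_mm,
        duration_s=max_session_s, seed=seed,
    )
    signal_axes, bubble_axes = generate_trial_parts(sess_cfg, p)
    n_steps = len(signal_axes)
    gate = FilterConfig(p.gate_um)

    state = ControllerState.fresh(ctrl_cfg)
    rows = []
    s_hist = np.zeros(n_steps)
    delivered_total = 0.0
    session_max: float | None = None
    stop_time: float | None = None
    appetite_at_stop: float | None = None

    for step in range(n_steps):
        t = step * dt
        appetite = tank.appetite
        axes = signal_axes[step] * appetite + bubble_axes[step]
        s = float(np.abs(amplitude_filter(axes, gate)).sum())
        s_hist[step] = s
        state.push_sample(s)

        delivered = state.feeder_speed_gps * dt
        delivered_total += delivered
        tank_step(tank, delivered, dt)

        pred_sum = np.nan
        out_val = np.nan
        if (step + 1) % decision_steps == 0 and not state.stopped:
            start = step + 1 - ctrl_cfg.buffer_len
            context = np.empty((ctrl_cfg.buffer_len, N_FEATURES))
            context[:, 0] = s_hist[start : step + 1]
            context[:, 1] = np.arange(start, step + 1) * dt
            context[:, 2] = config.size_g
            context[:, 3] = config.density
            context[:, 4] = state.feeder_speed_gps
            context[:, 5] = config.pellet_mm
            trajectory = np.asarray(predict(model, context), dtype=float)
            pred_sum = float(trajectory.sum())
            session_max = pred_sum if session_max is None else max(session_max, pred_sum)
            if session_max > 0:
                out_val = proportional_output(pred_sum, session_max,
                                              ctrl_cfg.output_scale)
            state, command = controller_step(state, trajectory, ctrl_cfg)
            if command == "stop" and stop_time is None:
                stop_time = t + dt
                appetite_at_stop = tank.appetite
        rows.append(
            {"t": t, "s_um": s, "buffer_full": step + 1 >= ctrl_cfg.buffer_len,
             "predicted_sum_um": pred_sum, "decline_count": state.decline_count,
             "feeder_speed_gps": state.feeder_speed_gps, "out_0_255": out_val}
        )

    if stop_time is None:
        warnings.warn("session reached maximum length without a stop command",
                      stacklevel=2)
    residual = tank.pending_g
    return SessionResult(
        total_fed_g=delivered_total,
        residual_g=residual,
        rfr_pct=rfr(residual, delivered_total),
        stop_time_s=stop_time,
        consumed_g=tank.consumed_g,
        appetite_at_stop=appetite_at_stop,
        seed=seed,
        command_log=pd.DataFrame(rows),
    )
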