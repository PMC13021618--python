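"""Stop-feeding decision logic, satiation tank and closed-loop sessions."""

import numpy as np
import pytest

from vibrofeed import control as ctl
from vibrofeed import synthetic as syn


class _StubModel:
    """Stands in for a trained trajectory forecaster in cadence tests."""

    class _Cfg:
        output_dim = 50

    model_cfg = _Cfg()


def _declining(level=100.0):
    return np.concatenate([np.full(25, level), np.full(25, 0.5 * level)])


def _flat(level=100.0):
    return np.full(50, level)


class TestDetectDecline:
    @pytest.mark.parametrize("first,second,expected", [
        (100.0, 89.0, True),   # strictly below 0.9x
        (100.0, 90.0, False),  # boundary: not strict
        (0.0, 0.0, False),     # degenerate zeros
        (100.0, 95.0, False),
        (50.0, 44.0, True),
    ])
    def test_decision_table(self, first, second, expected):
        pred = np.concatenate([np.full(25, first), np.full(25, second)])
        assert ctl.detect_decline(pred, 0.9) is expected

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            ctl.detect_decline(np.ones(49))


class TestControllerStep:
    def test_two_consecutive_declines_stop_on_second(self):
        cfg = ctl.ControllerConfig()
        state = ctl.ControllerState.fresh(cfg)
        state, cmd = ctl.controller_step(state, _declining(), cfg)
        assert cmd == "maintain" and state.decline_count == 1
        state, cmd = ctl.controller_step(state, _declining(), cfg)
        assert cmd == "stop" and state.stopped

    def test_non_decline_resets_counter(self):
        cfg = ctl.ControllerConfig()
        state = ctl.ControllerState.fresh(cfg)
        state, _ = ctl.controller_step(state, _declining(), cfg)
        state, _ = ctl.controller_step(state, _flat(), cfg)
        assert state.decline_count == 0
        state, cmd = ctl.controller_step(state, _declining(), cfg)
        assert cmd == "maintain" and not state.stopped

    def test_fresh_state_maintains_initial_speed(self):
        cfg = ctl.ControllerConfig()
        state = ctl.ControllerState.fresh(cfg)
        state, cmd = ctl.controller_step(state, _flat(), cfg)
        assert cmd == "maintain"
        assert state.feeder_speed_gps == 2.0

    def test_step_after_stop_warns_and_noops(self):
        cfg = ctl.ControllerConfig()
        state = ctl.ControllerState.fresh(cfg)
        state.stopped = True
        with pytest.warns(UserWarning):
            state, cmd = ctl.controller_step(state, _flat(), cfg)
        assert cmd == "stop"

    def test_monotone_increasing_stream_never_stops(self):
        cfg = ctl.ControllerConfig()
        state = ctl.ControllerState.fresh(cfg)
        for k in range(50):
            pred = np.linspace(k, k + 10, 50)
            state, cmd = ctl.controller_step(state, pred, cfg)
        assert not state.stopped and state.decline_count == 0

    def test_stricter_ratio_never_stops_earlier(self):
        # a lower decline ratio demands a deeper drop, so on the same stream
        # the stop index cannot come earlier
        rng = np.random.default_rng(0)
        stream = [
            np.full(25, a).tolist() + np.full(25, b).tolist()
            for a, b in rng.uniform(1, 100, size=(40, 2))
        ]
        stops = {}
        for ratio in (0.5, 0.9):
            cfg = ctl.ControllerConfig(decline_ratio=ratio)
            state = ctl.ControllerState.fresh(cfg)
            stop_at = None
            for k, pred in enumerate(stream):
                state, cmd = ctl.controller_step(state, np.array(pred), cfg)
                if cmd == "stop":
                    stop_at = k
                    break
            stops[ratio] = stop_at if stop_at is not None else len(stream)
        assert stops[0.5] >= stops[0.9]


class TestProportionalOutput:
    @pytest.mark.parametrize("pred,maxi,expected", [
        (500.0, 500.0, 255),
        (0.0, 500.0, 0),
        (250.0, 500.0, 128),  # round half up
        (1000.0, 500.0, 255),  # clamped
    ])
    def test_mapping(self, pred, maxi, expected):
        assert ctl.proportional_output(pred, maxi) == expected

    def test_nonpositive_session_max_rejected(self):
        with pytest.raises(ValueError):
            ctl.proportional_output(10.0, 0.0)


class TestRfr:
    @pytest.mark.parametrize("residual,total,expected", [
        (0.0, 50.0, 0.0),
        (1.0, 100.0, 1.0),
        (4.25, 64.6, 6.58),
    ])
    def test_examples(self, residual, total, expected):
        assert ctl.rfr(residual, total) == pytest.approx(expected, abs=0.005)

    def test_invalid_masses_rejected(self):
        with pytest.raises(ValueError):
            ctl.rfr(1.0, 0.0)
        with pytest.raises(ValueError):
            ctl.rfr(-1.0, 10.0)


class TestTankStep:
    def test_satiated_fish_eat_nothing(self):
        tank = ctl.TankModel(consumed_g=1e9)
        assert tank.appetite == 0.0
        eaten = ctl.tank_step(tank, delivered_g=0.2, dt_s=0.1)
        assert eaten == 0.0 and tank.pending_g == pytest.approx(0.2)

    def test_hungry_fish_clear_modest_delivery(self):
        tank = ctl.TankModel()
        eaten = ctl.tank_step(tank, delivered_g=0.2, dt_s=0.1)
        assert eaten == pytest.approx(0.2)
        assert tank.pending_g == 0.0

    def test_mass_conservation_identity(self):
        rng = np.random.default_rng(1)
        tank = ctl.TankModel(size_g=50, density=10)
        delivered_total = 0.0
        for _ in range(500):
            d = float(rng.uniform(0, 0.5))
            delivered_total += d
            ctl.tank_step(tank, d, 0.1)
            assert delivered_total == pytest.approx(tank.consumed_g + tank.pending_g)


class TestSimulateSession:
    def test_always_declining_model_stops_after_two_cycles(self, monkeypatch):
        monkeypatch.setattr(ctl, "predict", lambda model, ctx: _declining())
        res = ctl.simulate_session(
            syn.TrialConfig(size_g=300, density=30), ctl.ControllerConfig(),
            _StubModel(), seed=1, max_session_s=30.0,
        )
        assert res.stop_time_s == pytest.approx(10.0)
        assert res.total_fed_g == pytest.approx(20.0)

    def test_never_declining_model_times_out_with_warning(self, monkeypatch):
        monkeypatch.setattr(ctl, "predict", lambda model, ctx: _flat())
        with pytest.warns(UserWarning, match="maximum length"):
            res = ctl.simulate_session(
                syn.TrialConfig(size_g=300, density=30), ctl.ControllerConfig(),
                _StubModel(), seed=1, max_session_s=20.0,
            )
        assert res.stop_time_s is None

    def test_scalar_model_rejected(self):
        class _Scalar:
            class _Cfg:
                output_dim = 1
            model_cfg = _Cfg()

        with pytest.raises(ValueError, match="trajectory"):
            ctl.simulate_session(syn.TrialConfig(), ctl.ControllerConfig(),
                                 _Scalar(), seed=0)

    def test_closed_loop_session_bookkeeping(self, trajectory_lstm):
        res = ctl.simulate_session(
            syn.TrialConfig(size_g=300, density=30), ctl.ControllerConfig(),
            trajectory_lstm, seed=3,
        )
        # feed-mass conservation: delivered = consumed + pending
        assert res.total_fed_g == pytest.approx(res.consumed_g + res.residual_g)
        assert res.rfr_pct == pytest.approx(100 * res.residual_g / res.total_fed_g)
        assert res.stop_time_s is not None
        expected_cols = {"t", "s_um", "buffer_full", "predicted_sum_um",
                         "decline_count", "feeder_speed_gps", "out_0_255"}
        assert expected_cols <= set(res.command_log.columns)
        # feeder speed is zero after the stop command
        after = res.command_log[res.command_log.t > res.stop_time_s]
        assert np.all(after.feeder_speed_gps == 0.0)

    def test_sessions_reproducible_for_fixed_seed(self, trajectory_lstm):
        r1 = ctl.simulate_session(syn.TrialConfig(size_g=300, density=30),
                                  ctl.ControllerConfig(), trajectory_lstm, seed=5)
        r2 = ctl.simulate_session(syn.TrialConfig(size_g=300, density=30),
                                  ctl.ControllerConfig(), trajectory_lstm, seed=5)
        assert r1.rfr_pct == r2.rfr_pct
        assert r1.stop_time_s == r2.stop_time_s
        np.testing.assert_array_equal(r1.command_log.s_um, r2.command_log.s_um)
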