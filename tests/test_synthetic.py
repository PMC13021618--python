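"""Calibration solves and statistical fidelity of the trial generator."""

import numpy as np
import pytest

from vibrofeed import characterization as chz
from vibrofeed import signal_processing as sig
from vibrofeed import synthetic as syn


class TestCalibrateGroupMeans:
    def test_size_experiment_solution(self):
        mu = syn.calibrate_group_means((50, 150, 300), 1.7316, 236.41, 2.097)
        np.testing.assert_allclose(mu, [377.93, 404.58, 792.52], atol=0.01)

    def test_density_experiment_solution(self):
        mu = syn.calibrate_group_means((20, 40, 60), 5.4250, 47.11, 2.419)
        np.testing.assert_allclose(mu, [152.93, 269.48, 369.93], atol=0.01)

    @pytest.mark.parametrize("levels,slope,intercept,ratio", [
        ((50, 150, 300), 1.7316, 236.41, 2.097),
        ((20, 40, 60), 5.4250, 47.11, 2.419),
        ((1, 2, 3), 0.5, 10.0, 1.2),
    ])
    def test_ols_refit_recovers_line(self, levels, slope, intercept, ratio):
        mu = syn.calibrate_group_means(levels, slope, intercept, ratio)
        fit = chz.fit_line(np.array(levels), mu)
        assert fit.slope == pytest.approx(slope, rel=1e-9)
        assert fit.intercept == pytest.approx(intercept, rel=1e-9)
        assert mu[2] / mu[0] == pytest.approx(ratio, rel=1e-9)

    def test_line_consistent_ratio_gives_zero_residuals(self):
        slope, intercept = 2.0, 100.0
        levels = (10.0, 20.0, 30.0)
        ratio = (intercept + slope * levels[2]) / (intercept + slope * levels[0])
        mu = syn.calibrate_group_means(levels, slope, intercept, ratio)
        np.testing.assert_allclose(mu, intercept + slope * np.array(levels), rtol=1e-9)

    def test_invalid_inputs_rejected(self):
        with pytest.raises(syn.CalibrationError):
            syn.calibrate_group_means((1, 1, 2), 1.0, 0.0, 2.0)
        with pytest.raises(syn.CalibrationError):
            syn.calibrate_group_means((1, 2, 3), 1.0, 0.0, -1.0)


class TestFactorLoadings:
    def test_published_targets(self):
        w = syn.factor_loadings((0.93, 0.88, 0.91))
        np.testing.assert_allclose(
            w.as_array(), [0.94834, 0.98066, 0.92795], atol=1e-5
        )
        assert w.w_y * w.w_z == pytest.approx(0.91, abs=1e-12)
        assert w.w_x * w.w_y == pytest.approx(0.93, abs=1e-12)
        assert w.w_x * w.w_z == pytest.approx(0.88, abs=1e-12)

    def test_perfect_correlation(self):
        w = syn.factor_loadings((1.0, 1.0, 1.0))
        np.testing.assert_allclose(w.as_array(), 1.0)

    def test_symmetric_case(self):
        w = syn.factor_loadings((0.81, 0.81, 0.81))
        np.testing.assert_allclose(w.as_array(), 0.9, rtol=1e-12)

    def test_infeasible_triple_names_bound(self):
        with pytest.raises(syn.CalibrationError, match="> 1"):
            syn.factor_loadings((0.9, 0.2, 0.9))

    def test_out_of_range_rho_rejected(self):
        with pytest.raises(syn.CalibrationError):
            syn.factor_loadings((0.0, 0.5, 0.5))


class TestPeakTimeModel:
    @pytest.mark.parametrize("v,expected", [(3.0, 20.0), (1.0, 35.0), (2.0, 27.5)])
    def test_linear_advance_with_feed_rate(self, v, expected):
        assert syn.peak_time_model(v) == pytest.approx(expected)

    def test_clamped_inside_trial(self):
        assert syn.peak_time_model(10.0) == 5.0
        assert syn.peak_time_model(0.1, duration_s=30.0) == 25.0

    def test_nonpositive_rate_rejected(self):
        with pytest.raises(ValueError):
            syn.peak_time_model(0.0)


class TestMeanPeak:
    def test_size_experiment_condition(self):
        cfg = syn.TrialConfig(size_g=300, density=30, feed_rate=1, pellet_mm=5)
        assert syn.mean_peak(cfg) == pytest.approx(792.52, abs=0.01)

    def test_density_experiment_condition(self):
        cfg = syn.TrialConfig(size_g=50, density=60, feed_rate=1, pellet_mm=5)
        assert syn.mean_peak(cfg) == pytest.approx(369.93, abs=0.01)

    def test_anchor_condition(self):
        assert syn.mean_peak(syn.TrialConfig()) == pytest.approx(377.93, abs=0.01)

    def test_extrapolation_clamped_with_warning(self):
        cfg = syn.TrialConfig(size_g=1000, density=30, feed_rate=1, pellet_mm=5)
        with pytest.warns(UserWarning, match="clamped"):
            mu = syn.mean_peak(cfg)
        assert mu > 0


class TestEnvelope:
    def test_zero_at_origin_and_peak_at_t_peak(self):
        t = np.linspace(0, 120, 4801)
        env = syn.envelope(t, 35.0, 6.0)
        assert env[0] == 0.0
        assert t[np.argmax(env)] == pytest.approx(35.0, abs=0.05)
        assert env.max() == pytest.approx(1.0, abs=1e-9)

    def test_monotone_increasing_before_peak(self):
        t = np.linspace(0.1, 35.0, 500)
        env = syn.envelope(t, 35.0, 6.0)
        assert np.all(np.diff(env) > 0)


class TestGenerateTrial:
    def test_seeded_determinism(self):
        cfg = syn.TrialConfig(seed=99)
        t1, t2 = syn.generate_trial(cfg), syn.generate_trial(cfg)
        np.testing.assert_array_equal(t1.x, t2.x)
        np.testing.assert_array_equal(t1.z, t2.z)

    def test_noiseless_peak_window_contains_t_peak(self):
        cfg = syn.TrialConfig(size_g=300, density=30, feed_rate=3, pellet_mm=5, seed=4)
        tr = syn.generate_trial(cfg, noiseless=True)
        s = sig.triaxial_sum(tr, sig.FilterConfig(0.0))
        pt = chz.peak_time(sig.window_sums(s))
        assert abs(pt - 20.0) <= 2.5 + 1e-9

    def test_interaxis_correlations_hit_targets(self):
        tr = syn.generate_trial(syn.TrialConfig(seed=7))
        corr = sig.interaxis_correlation(tr)
        for got, want in zip(corr.as_tuple(), (0.93, 0.88, 0.91)):
            assert got == pytest.approx(want, abs=0.03)

    def test_duration_shorter_than_window_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_trial(syn.TrialConfig(duration_s=3.0))

    def test_noiseless_peak_recovery_exact_to_two_percent(self):
        # over 50 noiseless trials per size level the mean extracted peak
        # matches the calibrated group mean
        for level in (50.0, 150.0, 300.0):
            cfg0 = syn.TrialConfig(size_g=level, density=30, feed_rate=1, pellet_mm=5)
            mu = syn.mean_peak(cfg0)
            peaks = []
            for k in range(50):
                cfg = syn.TrialConfig(size_g=level, density=30, feed_rate=1,
                                      pellet_mm=5, seed=k)
                tr = syn.generate_trial(cfg, noiseless=True)
                s = sig.triaxial_sum(tr, sig.FilterConfig(0.0))
                peaks.append(chz.peak_displacement(sig.window_sums(s))[0])
            assert np.mean(peaks) == pytest.approx(mu, rel=0.02)

    def test_noiseless_zero_crossing_recovers_base_frequency(self):
        cfg = syn.TrialConfig(size_g=300, density=30, feed_rate=1, pellet_mm=3, seed=2)
        tr = syn.generate_trial(cfg, noiseless=True)
        s = sig.triaxial_sum(tr, sig.FilterConfig(0.0))
        freq = chz.zero_crossing_frequency(chz.active_segment(s), tr.fs)
        assert freq == pytest.approx(2.0, rel=0.05)

    def test_bubble_noise_removed_by_gate(self):
        # with the feeding signal suppressed, gated sums are exactly zero
        p = syn.GeneratorParams()
        cfg = syn.TrialConfig(seed=6)
        _, bubble = syn.generate_trial_parts(cfg, p)
        gated = sig.amplitude_filter(bubble.ravel(), sig.FilterConfig(p.gate_um))
        assert np.all(gated == 0)


class TestGenerateDataset:
    def test_default_design_has_408_trials(self):
        design = syn.default_design()
        assert sum(reps for _, _, reps in design) == 408

    def test_single_replicate_gives_twelve_conditions(self):
        ds = syn.generate_dataset(design=syn.default_design(replicates=1),
                                  master_seed=1)
        assert len(ds.traces) == 12
        assert len(ds.manifest) == 12
        assert ds.manifest.experiment.value_counts().to_dict() == {
            "size": 3, "density": 3, "rate": 3, "pellet": 3
        }

    def test_master_seed_reproducibility(self):
        d1 = syn.generate_dataset(design=syn.default_design(replicates=1), master_seed=5)
        d2 = syn.generate_dataset(design=syn.default_design(replicates=1), master_seed=5)
        assert d1.manifest.equals(d2.manifest)
        for a, b in zip(d1.traces, d2.traces):
            np.testing.assert_array_equal(a.x, b.x)

    def test_empty_design_rejected(self):
        with pytest.raises(ValueError):
            syn.generate_dataset(design=[])


class TestFrequencyReduction:
    def test_published_palatability_effect(self):
        assert syn.frequency_reduction(syn.GeneratorParams(), "2#", "4#") == \
            pytest.approx(42.0)

    def test_identity(self):
        assert syn.frequency_reduction(syn.GeneratorParams(), 3.0, 3.0) == 0.0

    def test_custom_factor_table(self):
        p = syn.GeneratorParams(osc_freq_factors={3.0: 1.0, 5.0: 0.5, 7.0: 0.75})
        assert syn.frequency_reduction(p, 3.0, 5.0) == pytest.approx(50.0)

    def test_unknown_grade_rejected(self):
        with pytest.raises(KeyError):
            syn.frequency_reduction(syn.GeneratorParams(), "9#", "4#")
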