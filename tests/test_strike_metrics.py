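"""Strike-variable computation: normalization, impulse, slip logic, recovery."""

import dataclasses

import numpy as np
import pytest

from strikelab.metrics import (
    fore_aft_impulse,
    slip_fraction,
    to_body_weights,
    trapz_between,
)
from strikelab.pipeline import AnalysisConfig, analyze_trial
from strikelab.smooth import NoStrikeError, StrikeEvents
from strikelab.synthetic import (
    Constant,
    HalfSine,
    StrikeScenario,
    generate_direct_profile_trial,
    generate_two_mass_trial,
)


class TestBodyWeights:
    def test_unit_case(self):
        assert to_body_weights(9.81, 1.0) == pytest.approx(1.0, rel=1e-12)

    def test_zero_force(self):
        assert to_body_weights(0.0, 0.58) == 0.0

    def test_typical_juvenile_mass(self):
        assert to_body_weights(5.0, 0.58) == pytest.approx(
            5.0 / (0.58 * 9.81), rel=1e-12
        )

    def test_nonpositive_mass_rejected(self):
        with pytest.raises(ValueError, match="mass"):
            to_body_weights(1.0, 0.0)


class TestImpulse:
    def _events(self, a, b):
        return StrikeEvents(t_onset=a, t_end_forward=b)

    def test_constant_force(self):
        t = np.arange(500) / 1000.0
        out = fore_aft_impulse(t, np.ones(t.size), self._events(0.1, 0.2))
        assert out["fa_impulse"] == pytest.approx(0.1, rel=1e-12)

    def test_half_sine_closed_form(self):
        t = np.arange(500) / 1000.0
        T0, dur = 0.1, 0.1
        f = np.where(
            (t >= T0) & (t <= T0 + dur), np.sin(np.pi * (t - T0) / dur), 0.0
        )
        out = fore_aft_impulse(t, f, self._events(T0, T0 + dur))
        assert out["fa_impulse"] == pytest.approx(2 * dur / np.pi, rel=1e-3)

    def test_antisymmetric_force_integrates_to_zero(self):
        t = np.arange(501) / 1000.0
        f = np.sin(2 * np.pi * (t - 0.1) / 0.2)  # full period inside window
        out = fore_aft_impulse(t, f, self._events(0.1, 0.3))
        assert out["fa_impulse"] == pytest.approx(0.0, abs=1e-12)

    def test_additivity_over_adjacent_windows(self, rng):
        t = np.arange(1000) / 1000.0
        f = rng.normal(size=t.size)
        a, b, c = 0.1234, 0.45678, 0.91  # off-grid split points
        whole = trapz_between(t, f, a, c)
        parts = trapz_between(t, f, a, b) + trapz_between(t, f, b, c)
        assert parts == pytest.approx(whole, abs=1e-9)

    def test_bw_normalization(self):
        t = np.arange(500) / 1000.0
        out = fore_aft_impulse(
            t, np.ones(t.size), self._events(0.0, 0.1), mass_kg=1.0, g=9.81
        )
        assert out["fa_impulse_bw_s"] == pytest.approx(0.1 / 9.81, rel=1e-9)

    def test_empty_window_rejected(self):
        t = np.arange(100) / 1000.0
        with pytest.raises(ValueError, match="window"):
            trapz_between(t, np.ones(100), 0.05, 0.05)


class TestSlipFraction:
    MASS = 1.0 / 9.81  # body weight of exactly 1 N

    def test_ratio_below_threshold(self):
        f_v = np.ones(100)
        f_fa = np.full(100, 0.2)
        mx, pct, nex = slip_fraction(f_fa, f_v, 0.3, self.MASS)
        assert mx == pytest.approx(0.2)
        assert pct == 0.0 and nex == 0

    def test_ratio_above_threshold_everywhere(self):
        mx, pct, _ = slip_fraction(np.full(50, 0.5), np.ones(50), 0.3, self.MASS)
        assert (mx, pct) == (0.5, 100.0)

    def test_exact_quarter_fraction(self):
        f_fa = np.concatenate([np.full(25, 0.6), np.full(75, 0.1)])
        _, pct, _ = slip_fraction(f_fa, np.ones(100), 0.3, self.MASS)
        assert pct == 25.0

    def test_low_vertical_samples_excluded(self):
        f_v = np.concatenate([np.ones(80), np.full(20, 0.01)])  # below 0.05 BW
        f_fa = np.full(100, 0.5)
        mx, pct, nex = slip_fraction(f_fa, f_v, 0.3, self.MASS)
        assert nex == 20
        assert pct == 100.0  # only valid samples counted
        assert mx == pytest.approx(0.5)

    def test_all_samples_excluded_rejected(self):
        with pytest.raises(ValueError, match="excluded"):
            slip_fraction(np.ones(10), np.zeros(10), 0.3, self.MASS)


class TestComputeMetrics:
    def test_direct_profile_recovery_within_2pct(self, cal_meta):
        # calibration trial: known amplitudes, full pipeline recovery
        bw = cal_meta.body_weight_N
        force, kin, truth = generate_direct_profile_trial(
            {
                "fa": HalfSine(0.8 * bw, 0.22, 0.08),
                "vertical": Constant(1.2 * bw),
            },
            (0.2, 0.32),
            cal_meta,
        )
        res = analyze_trial(force, kin, cal_meta)
        m = res.metrics
        assert m.max_fa_force == pytest.approx(truth.max_fa_force_bw, rel=0.02)
        assert m.max_vertical_force == pytest.approx(
            truth.max_vertical_force_bw, rel=0.02
        )
        assert m.max_total_force == pytest.approx(truth.max_total_force_bw, rel=0.02)
        assert m.max_fa_v_ratio == pytest.approx(truth.max_fa_v_ratio, rel=0.02)
        assert m.fa_impulse == pytest.approx(truth.fa_impulse, rel=0.02)
        assert m.strike_distance == pytest.approx(truth.strike_distance, rel=0.02)
        assert m.max_head_velocity == pytest.approx(truth.max_head_velocity, rel=0.02)
        assert m.max_head_acceleration == pytest.approx(
            truth.max_head_acceleration, rel=0.05
        )

    def test_min_jerk_strike_distance_calibration(self, clean_walled):
        # head travels 0.21 m; recovered strike distance within 1 mm
        force, kin, meta, _ = generate_two_mass_trial(clean_walled)
        res = analyze_trial(force, kin, meta)
        assert res.metrics.strike_distance == pytest.approx(0.21, abs=1e-3)

    def test_zero_motion_trial_raises_no_strike(self):
        sc = StrikeScenario(
            strike_distance=0.0, noise_sd_force=0.0, noise_sd_position=0.0
        )
        force, kin, meta, _ = generate_two_mass_trial(sc)
        with pytest.raises(NoStrikeError):
            analyze_trial(force, kin, meta)

    @pytest.mark.parametrize("setup", ["open", "walled"])
    @pytest.mark.parametrize("seed", [0, 7])
    def test_total_force_dominates_components(self, setup, seed):
        sc = StrikeScenario(setup=setup, seed=seed)
        force, kin, meta, _ = generate_two_mass_trial(sc)
        m = analyze_trial(force, kin, meta).metrics
        assert m.max_total_force >= m.max_fa_force - 1e-12
        assert m.max_total_force >= m.max_vertical_force - 1e-12

    @pytest.mark.parametrize("setup", ["open", "walled"])
    def test_slip_statistics_are_consistent(self, setup):
        sc = StrikeScenario(setup=setup, seed=3)
        force, kin, meta, _ = generate_two_mass_trial(sc)
        m = analyze_trial(force, kin, meta).metrics
        if m.pct_above_slip > 0:
            assert m.max_fa_v_ratio > meta.mu
        if m.max_fa_v_ratio <= meta.mu:
            assert m.pct_above_slip == 0.0

    def test_open_vs_walled_slip_contrast(self):
        # the generator's defining contrast: tail recoil keeps open-setup
        # trials at/below the slip threshold while walled trials exceed it
        open_sc = StrikeScenario(setup="open", seed=5)
        walled_sc = dataclasses.replace(open_sc, setup="walled")
        m_open = analyze_trial(*generate_two_mass_trial(open_sc)[:3]).metrics
        m_walled = analyze_trial(*generate_two_mass_trial(walled_sc)[:3]).metrics
        assert m_open.pct_above_slip <= 5.0
        assert m_walled.pct_above_slip > m_open.pct_above_slip
        assert m_walled.max_fa_v_ratio > m_open.max_fa_v_ratio

    def test_tare_subtracts_resting_weight(self, clean_walled):
        force, kin, meta, _ = generate_two_mass_trial(clean_walled)
        raw = analyze_trial(force, kin, meta).metrics
        tared = analyze_trial(
            force, kin, meta, AnalysisConfig(tare_vertical=True)
        ).metrics
        assert tared.max_vertical_force == pytest.approx(
            raw.max_vertical_force - 1.0, abs=0.02
        )
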