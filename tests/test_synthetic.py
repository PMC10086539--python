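"""Generator correctness: analytic extrema, mechanics, calibration profiles."""

import numpy as np
import pytest

from strikelab.synthetic import (
    Constant,
    HalfSine,
    InfeasibleScenarioError,
    MINJERK_PEAK_ACCEL,
    PiecewiseConstant,
    StrikeScenario,
    Trapezoid,
    generate_cohort,
    generate_direct_profile_trial,
    generate_min_jerk_strike,
    generate_two_mass_trial,
    load_scenario,
)


def _clean(**kw) -> StrikeScenario:
    return StrikeScenario(noise_sd_force=0.0, noise_sd_position=0.0, **kw)


class TestMinJerk:
    def test_analytic_peak_speed_and_acceleration(self):
        sc = _clean(strike_distance=0.20, strike_duration=0.10, setup="walled")
        _, truth = generate_min_jerk_strike(sc)
        assert truth.max_head_velocity == pytest.approx(3.75, rel=1e-12)
        assert truth.max_head_acceleration == pytest.approx(
            10.0 / np.sqrt(3.0) * 0.20 / 0.10**2, rel=1e-12
        )
        assert truth.max_head_acceleration == pytest.approx(115.47, rel=1e-4)

    def test_zero_distance_is_stationary(self):
        kin, truth = generate_min_jerk_strike(_clean(strike_distance=0.0))
        assert truth.max_head_velocity == 0.0
        assert np.ptp(kin.head_x) == 0.0
        assert np.ptp(kin.head_y) == 0.0

    def test_too_short_duration_rejected(self):
        with pytest.raises(ValueError, match="4 video frames"):
            _clean(strike_duration=0.005)


class TestTwoMassTrial:
    def test_walled_peak_force_is_head_mass_times_accel(self):
        # peak head acceleration set to 100 m/s^2 with a 0.2 kg head:
        # stationary tail means peak fore-aft plate force = 20 N
        T = 0.1
        D = 100.0 * T**2 / MINJERK_PEAK_ACCEL
        sc = _clean(
            strike_distance=D,
            strike_duration=T,
            mass=1.0,
            head_mass_fraction=0.2,
            setup="walled",
        )
        _, _, meta, truth = generate_two_mass_trial(sc)
        peak_fa_N = truth.max_fa_force_bw * meta.body_weight_N
        assert peak_fa_N == pytest.approx(20.0, rel=1e-3)  # grid-sampled peak

    def test_open_mode_respects_slip_cap(self, clean_open):
        _, _, _, truth = generate_two_mass_trial(clean_open)
        ratio = np.abs(truth.debug["f_fa"]) / truth.debug["f_v"]
        assert np.max(ratio) <= clean_open.mu + 1e-6
        assert truth.pct_above_slip == 0.0

    @pytest.mark.parametrize("setup", ["walled", "open"])
    def test_impulse_momentum_identity(self, setup):
        # trapezoidal ground impulse over the strike window equals the total
        # horizontal momentum change of both masses to 1e-6 relative
        sc = _clean(setup=setup)
        _, _, _, truth = generate_two_mass_trial(sc)
        d = truth.debug
        t, lo, hi = d["time"], *d["window"]
        w = (t >= lo - 1e-12) & (t <= hi + 1e-12)
        impulse = np.trapezoid(d["f_fa"][w], t[w])
        dv_h = d["v_h"][w][-1] - d["v_h"][w][0]
        dv_t = d["v_t"][w][-1] - d["v_t"][w][0]
        dp = d["m_h"] * dv_h + d["m_t"] * dv_t
        scale = d["m_h"] * truth.max_head_velocity
        assert abs(impulse - dp) / scale < 1e-6

    def test_bit_identical_under_same_seed(self):
        sc = StrikeScenario(seed=42)
        f1, k1, _, _ = generate_two_mass_trial(sc)
        f2, k2, _, _ = generate_two_mass_trial(sc)
        assert np.array_equal(f1.fx, f2.fx)
        assert np.array_equal(f1.fz, f2.fz)
        assert np.array_equal(k1.head_x, k2.head_x)
        assert np.array_equal(k1.tail_y, k2.tail_y)

    def test_different_seed_changes_noise(self):
        f1, _, _, _ = generate_two_mass_trial(StrikeScenario(seed=1))
        f2, _, _, _ = generate_two_mass_trial(StrikeScenario(seed=2))
        assert not np.array_equal(f1.fx, f2.fx)

    def test_infeasible_open_cap_names_sample(self):
        sc = _clean(setup="open", max_tail_accel=1.0)
        with pytest.raises(InfeasibleScenarioError, match="sample"):
            generate_two_mass_trial(sc)

    def test_kinematics_follow_azimuth(self):
        sc = _clean(strike_azimuth=np.pi / 4, setup="walled")
        kin, _ = generate_min_jerk_strike(sc)
        dx = kin.head_x[-1] - kin.head_x[0]
        dy = kin.head_y[-1] - kin.head_y[0]
        assert np.arctan2(dy, dx) == pytest.approx(np.pi / 4, abs=1e-9)
        assert np.hypot(dx, dy) == pytest.approx(sc.strike_distance, abs=1e-12)


class TestDirectProfile:
    def test_half_sine_impulse_closed_form(self, cal_meta):
        _, _, truth = generate_direct_profile_trial(
            {"fa": HalfSine(1.0, 0.22, 0.10)}, (0.2, 0.32), cal_meta
        )
        assert truth.fa_impulse == pytest.approx(2.0 * 1.0 * 0.10 / np.pi, rel=1e-12)

    def test_constructed_slip_fraction(self, cal_meta):
        # ratio above mu in exactly 25 of the first 100 window samples ->
        # remaining samples sit below threshold, window has 101 grid samples
        bw = cal_meta.body_weight_N
        dt = 1.0 / cal_meta.force_rate
        t0 = 0.2
        edges = (t0, t0 + 25 * dt, t0 + 99 * dt)
        prof = PiecewiseConstant(edges, (0.6 * bw, 0.1 * bw))
        _, _, truth = generate_direct_profile_trial(
            {"fa": prof, "vertical": Constant(bw)},
            (t0, t0 + 99 * dt),
            cal_meta,
        )
        assert truth.pct_above_slip == pytest.approx(25.0, abs=1e-12)

    def test_zero_amplitude_profiles(self, cal_meta):
        _, _, truth = generate_direct_profile_trial(
            {"fa": HalfSine(0.0, 0.22, 0.05)}, (0.2, 0.32), cal_meta
        )
        assert truth.max_fa_force_bw == 0.0
        assert truth.fa_impulse == 0.0
        assert truth.max_fa_v_ratio == 0.0

    def test_support_outside_window_rejected(self, cal_meta):
        with pytest.raises(ValueError, match="support"):
            generate_direct_profile_trial(
                {"fa": HalfSine(1.0, 0.1, 0.5)}, (0.2, 0.32), cal_meta
            )

    def test_trapezoid_profile_peak_and_integral(self):
        p = Trapezoid(2.0, 0.1, 0.02, 0.05, 0.03)
        t = np.linspace(0.0, 0.3, 3001)
        y = p(t)
        assert y.max() == pytest.approx(2.0, rel=1e-6)
        assert np.trapezoid(y, t) == pytest.approx(p.integral(), rel=1e-3)


class TestCohort:
    def test_balanced_bookkeeping(self):
        df, _ = generate_cohort(4, 6, seed=1)
        assert len(df) == 48
        counts = df.groupby(["individual", "setup"]).size()
        assert (counts == 6).all()

    def test_degenerate_noiseless_cells(self):
        df, _ = generate_cohort(
            3,
            4,
            grand_mean=10.0,
            setup_effect=2.0,
            between_individual_sd=0.0,
            interaction_sd=0.0,
            residual_sd=0.0,
            seed=0,
        )
        open_vals = df.loc[df.setup == "open", "value"]
        walled_vals = df.loc[df.setup == "walled", "value"]
        assert (open_vals == 9.0).all()
        assert (walled_vals == 11.0).all()

    def test_negative_sd_rejected(self):
        with pytest.raises(ValueError, match="residual_sd"):
            generate_cohort(4, 6, residual_sd=-1.0)

    def test_reproducible_under_seed(self):
        df1, _ = generate_cohort(4, 6, seed=7)
        df2, _ = generate_cohort(4, 6, seed=7)
        assert np.array_equal(df1["value"].to_numpy(), df2["value"].to_numpy())


class TestScenarioConfig:
    @pytest.mark.parametrize(
        "kw",
        [
            {"strike_distance": -0.1},
            {"strike_duration": 0.0},
            {"head_mass_fraction": 0.0},
            {"mass": 0.0},
            {"mu": 0.0},
            {"setup": "arena"},
            {"noise_sd_force": -1.0},
        ],
    )
    def test_invalid_scenarios_rejected(self, kw):
        with pytest.raises(ValueError):
            StrikeScenario(**kw)

    def test_yaml_round_trip_and_unknown_key(self, tmp_path):
        good = tmp_path / "sc.yaml"
        good.write_text("strike_distance: 0.15\nsetup: walled\n")
        sc = load_scenario(good)
        assert sc.strike_distance == 0.15
        assert sc.setup == "walled"
        bad = tmp_path / "bad.yaml"
        bad.write_text("strike_distance: 0.15\nvenom: true\n")
        with pytest.raises(ValueError, match="venom"):
            load_scenario(bad)
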