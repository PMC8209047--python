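import numpy as np
import pandas as pd
import pytest

from flucgrowth import (KernelPair, NullTrajectory, ShiftKernel, SimConfig,
                        biomass_projection, fold_difference,
                        fraction_of_predicted_loss, growth_points,
                        jensen_rate, make_shift_kernels, make_signal,
                        paired_comparison, predict_gfluc,
                        simulate_tracks, steady_state_rate)

T_GRID = (30.0, 300.0, 900.0, 3600.0, 12 * 3600.0, 96 * 3600.0)
VARIANTS = ("A_value_matching", "B_clock_reset")


class TestJensenRate:
    def test_printed_reference(self):
        from flucgrowth import display_round
        assert jensen_rate(1.07, 2.86) == pytest.approx(1.965)
        assert display_round(jensen_rate(1.07, 2.86), 2) == 1.97

    def test_identity_and_midpoint(self):
        assert jensen_rate(1.3, 1.3) == 1.3
        assert jensen_rate(0.0, 2.0) == 1.0

    def test_non_finite_rejected(self):
        with pytest.raises(ValueError):
            jensen_rate(np.inf, 1.0)


def oracle_trajectory(kernels, signal, variant, t):
    """Event-by-event scalar re-implementation of the null trajectory."""
    ups = set(np.round(signal.shift_times("up"), 9))
    events = sorted(set(np.round(signal.shift_times(), 9)))
    out = np.empty(len(t))
    for j, tj in enumerate(t):
        mu = kernels.g_high if signal.concentration(0.0) == signal.c_high \
            else kernels.g_low
        t_seg, kern, tau0 = 0.0, None, 0.0
        for ev in events:
            if ev > tj:
                break
            # advance mu to just before this event
            if kern is not None:
                mu = float(kern(tau0 + ev - t_seg))
            if ev in ups:
                kern = kernels.up
                tau0 = kern.value_match_tau(mu) \
                    if variant == "A_value_matching" else 0.0
            else:
                kern = kernels.down
                tau0 = 0.0
            t_seg = ev
        out[j] = mu if kern is None else float(kern(tau0 + tj - t_seg))
    return out


class TestBuildNull:
    def test_single_upshift_reduces_to_the_kernel(self, default_kernels):
        sig = make_signal("single_shift", 0.1, 2.0, duration=8 * 3600.0,
                          shift_time=3 * 3600.0, first_phase="low")
        for variant in VARIANTS:
            traj = NullTrajectory(default_kernels, sig, variant)
            t = np.linspace(0, 8 * 3600.0, 400)
            expected = np.where(t < 3 * 3600.0, 1.07,
                                default_kernels.up(t - 3 * 3600.0))
            assert np.allclose(traj(t), expected, atol=1e-12)

    def test_step_kernels_alternate_exactly(self):
        k = make_shift_kernels(t_up_complete=0.0, t_down_complete=0.0,
                               drop_fraction=1.0)
        sig = make_signal("fluctuating", 0.1, 2.0, duration=2 * 3600.0,
                          period_T=1800.0, first_phase="high")
        traj = NullTrajectory(k, sig)
        t = np.arange(10.0, 2 * 3600.0, 60.0)
        expected = np.where(np.mod(t, 1800.0) < 900.0, 2.86, 1.07)
        assert np.allclose(traj(t), expected)

    @pytest.mark.parametrize("variant", VARIANTS)
    def test_matches_event_by_event_oracle(self, default_kernels, variant):
        sig = make_signal("fluctuating", 0.1, 2.0, duration=3600.0,
                          period_T=300.0, first_phase="high")
        traj = NullTrajectory(default_kernels, sig, variant)
        t = np.linspace(1.0, 3599.0, 257)
        assert np.allclose(traj(t),
                           oracle_trajectory(default_kernels, sig, variant,
                                             t),
                           atol=1e-9)

    def test_kernel_endpoint_mismatch_rejected(self):
        up = ShiftKernel("up", 1.07, 1.07, 2.86, 9000.0)
        down = ShiftKernel("down", 2.86, 0.107, 0.9, 18000.0)  # != up start
        sig = make_signal("fluctuating", 0.1, 2.0, duration=3600.0,
                          period_T=600.0)
        with pytest.raises(ValueError, match="endpoint"):
            NullTrajectory(KernelPair(up, down), sig)


class TestPredictGfluc:
    def test_step_kernels_predict_g_j_for_every_period(self):
        k = make_shift_kernels(t_up_complete=0.0, t_down_complete=0.0,
                               drop_fraction=1.0)
        pred = predict_gfluc(k, T_grid_s=T_GRID)
        assert np.allclose(pred.predicted_G_fluc, pred.G_J)

    @pytest.mark.parametrize("variant", VARIANTS)
    @pytest.mark.parametrize("shape", ["exponential", "linear"])
    def test_prediction_nondecreasing_in_period(self, variant, shape):
        k = make_shift_kernels(shape=shape)
        pred = predict_gfluc(k, variant, T_grid_s=T_GRID)
        assert np.all(pred.converged)
        assert np.all(np.diff(pred.predicted_G_fluc) >= -1e-12)

    @pytest.mark.parametrize("shape", ["exponential", "linear"])
    def test_deficit_area_bound_on_the_asymptote(self, shape):
        """|G_J - prediction| <= (A_up + A_down)/T, with the bound tight
        (equality up to quadrature error) once T/2 exceeds both completion
        times."""
        k = make_shift_kernels(shape=shape)
        pred = predict_gfluc(k, T_grid_s=T_GRID)
        area = k.up.deficit_area_h() + k.down.deficit_area_h()
        gap = pred.G_J - pred.predicted_G_fluc
        assert np.all(gap >= -1e-9)
        assert np.all(gap <= area / (pred.T_grid_s / 3600.0) + 1e-4)

    def test_long_period_prediction_approaches_g_j(self, default_kernels):
        pred = predict_gfluc(default_kernels, T_grid_s=[2000.0 * 3600.0])
        assert abs(pred.predicted_G_fluc[0] - 1.965) < 0.01

    def test_value_matching_never_below_clock_reset(self, default_kernels):
        a = predict_gfluc(default_kernels, "A_value_matching",
                          T_grid_s=T_GRID)
        b = predict_gfluc(default_kernels, "B_clock_reset", T_grid_s=T_GRID)
        assert np.all(a.predicted_G_fluc >= b.predicted_G_fluc - 1e-12)

    def test_bad_period_rejected(self, default_kernels):
        with pytest.raises(ValueError):
            predict_gfluc(default_kernels, T_grid_s=[0.0])

    def test_simulated_pipeline_matches_prediction(self, default_kernels,
                                                   default_map):
        """Closing the loop: tracks simulated under single-shift-kernel
        physiology in a T = 60 min wave yield a measured G_fluc within
        3 SEM of the null-model prediction for the same variant."""
        T = 3600.0
        sig = make_signal("fluctuating", 0.1, 2.0, duration=12 * 3600.0,
                          period_T=T, first_phase="high")
        cfg = SimConfig(seed=12, physiology="single_shift_kernel",
                        n_cells=250, size_noise_sd=0.01, cell_rate_sd=0.05,
                        day_effect_sd=0.0, mean_track_frames=60)
        res = simulate_tracks(sig, cfg, kernels=default_kernels)
        ss = steady_state_rate(growth_points(res.table))
        pred = predict_gfluc(default_kernels, "A_value_matching",
                             T_grid_s=[T])
        assert abs(ss.G - pred.predicted_G_fluc[0]) < 3 * ss.sem + 0.01


class TestBiomass:
    def test_daily_biomass_projections(self):
        m_fluc = biomass_projection(1.0, 1.93, 24.0)
        m_ave = biomass_projection(1.0, 2.31, 24.0)
        # one significant figure, as reported
        assert float(f"{m_fluc.M:.0e}") == 9e13
        assert float(f"{m_ave.M:.0e}") == 5e16

    def test_zero_growth_or_time_is_identity(self):
        assert biomass_projection(1.0, 0.0, 17.0).M == 1.0
        assert biomass_projection(3.0, 2.0, 0.0).M == 3.0

    def test_fold_difference_exceeds_500(self):
        fold = fold_difference(1.93, 2.31, 24.0)
        assert fold == pytest.approx(2.0 ** (0.38 * 24.0))
        assert fold > 500.0
        assert fold == pytest.approx(557.0, abs=1.0)

    def test_invalid_domain(self):
        with pytest.raises(ValueError):
            biomass_projection(0.0, 1.0, 1.0)
        with pytest.raises(ValueError):
            fold_difference(1.0, 2.0, -1.0)


class TestPairedComparison:
    def test_equal_ratios_give_zero_spread(self):
        df = pd.DataFrame({"replicate_day": ["d1", "d2"],
                           "G_fluc": [1.0, 1.2], "G_ave": [2.0, 2.4]})
        cs = paired_comparison(df, "G_ave")
        assert np.allclose(cs.per_day["pct_diff"], -50.0)
        assert cs.mean_pct_diff == pytest.approx(-50.0)
        assert cs.sd_pct_diff == 0.0

    def test_single_day_printed_bound(self):
        df = pd.DataFrame({"replicate_day": ["d1"], "G_fluc": [1.93],
                           "G_ave": [2.31]})
        cs = paired_comparison(df, "G_ave")
        assert cs.mean_pct_diff == pytest.approx(-16.45, abs=0.005)

    def test_g_j_reference_uses_per_day_rates(self):
        df = pd.DataFrame({"replicate_day": ["d1"], "G_fluc": [1.15],
                           "G_low": [1.07], "G_high": [2.86]})
        cs = paired_comparison(df, "G_J")
        assert cs.per_day["G_ref"].iloc[0] == pytest.approx(1.965)

    def test_pairing_removes_shared_day_variability(self):
        """With a shared day effect, paired percent differences are less
        dispersed than all-pairs unpaired differences."""
        rng = np.random.default_rng(3)
        day = rng.lognormal(0.0, 0.15, 12)
        g_fluc = 1.15 * day * rng.lognormal(0.0, 0.02, 12)
        g_ave = 2.31 * day * rng.lognormal(0.0, 0.02, 12)
        df = pd.DataFrame({"replicate_day": [f"d{i}" for i in range(12)],
                           "G_fluc": g_fluc, "G_ave": g_ave})
        cs = paired_comparison(df, "G_ave")
        unpaired = [(f - a) / a * 100.0 for f in g_fluc for a in g_ave]
        assert cs.sd_pct_diff < np.std(unpaired, ddof=1)

    def test_no_complete_pairs_rejected(self):
        df = pd.DataFrame({"replicate_day": ["d1"], "G_fluc": [np.nan],
                           "G_ave": [2.31]})
        with pytest.raises(ValueError):
            paired_comparison(df, "G_ave")


class TestFractionOfPredictedLoss:
    def test_limits(self):
        assert fraction_of_predicted_loss(2.31, 1.33, 1.33) == \
            pytest.approx(100.0)
        assert fraction_of_predicted_loss(2.31, 2.31, 1.33) == \
            pytest.approx(0.0)

    def test_arithmetic_example(self):
        assert fraction_of_predicted_loss(2.31, 1.93, 1.33) == \
            pytest.approx(100.0 * 0.38 / 0.98, rel=1e-9)

    def test_zero_predicted_loss_rejected(self):
        with pytest.raises(ValueError):
            fraction_of_predicted_loss(2.31, 2.0, 2.31)
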