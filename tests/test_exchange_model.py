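import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from relaxdisp.exchange_model import (
    PulseTrainError,
    TwoStateParams,
    admissible_grid,
    bm_r2eff,
    bm_r2eff_brute,
    bm_r2eff_grid,
    carver_richards_r2eff,
    dw_rad_per_s,
    n_pulses,
    pulse_train,
    simulate_series,
)
from relaxdisp.tables_io import SpectrometerContext

CTX8 = SpectrometerContext(800.4, 298.0, 0.030)
CTX6 = SpectrometerContext(600.03, 298.0, 0.030)


class TestTwoStateParams:
    def test_rate_decomposition(self):
        p = TwoStateParams(0.05, 500.0, 3.0, 12.0)
        assert p.k_AB_s1 + p.k_BA_s1 == pytest.approx(p.k_ex_s1, rel=1e-15)
        # detailed balance
        assert p.k_AB_s1 / p.k_BA_s1 == pytest.approx(p.p_B / p.p_A, rel=1e-12)

    @pytest.mark.parametrize("pb", [0.0, 0.6, -0.1])
    def test_population_bounds(self, pb):
        with pytest.raises(ValueError):
            TwoStateParams(pb, 500.0, 3.0, 12.0)


class TestPulseTrain:
    def test_minimum_grid_point(self):
        events = pulse_train(0.030, 66.7)
        pulses = [e for e in events if e[0] == "pulse"]
        delays = [e[1] for e in events if e[0] == "delay"]
        assert len(pulses) == 4
        assert delays[1] == pytest.approx(0.0075)
        assert sum(delays) == pytest.approx(0.030, rel=1e-12)

    def test_maximum_grid_point(self):
        assert n_pulses(0.030, 1000.0) == 60
        events = pulse_train(0.030, 1000.0)
        assert [e[1] for e in events if e[0] == "delay"][1] == pytest.approx(5e-4)

    def test_inadmissible_frequency(self):
        with pytest.raises(PulseTrainError, match="admissible"):
            pulse_train(0.030, 50.0)  # N = 3

    def test_n_not_divisible_by_four(self):
        with pytest.raises(PulseTrainError):
            pulse_train(0.030, 100.0)  # N = 6

    def test_train_symmetric_half_delays(self):
        delays = [e[1] for e in pulse_train(0.030, 133.3) if e[0] == "delay"]
        assert delays[0] == pytest.approx(delays[-1])
        assert delays[0] == pytest.approx(delays[1] / 2.0)


PARAM_GRID = list(itertools.product((0.02, 0.05, 0.1),
                                    (1000.0, 2000.0, 4000.0),
                                    (1.0, 2.0, 3.0)))


class TestBlochMcConnell:
    def test_no_exchange_when_pb_vanishes(self, nu_grid):
        p = TwoStateParams(1e-10, 500.0, 3.0, 12.0)
        np.testing.assert_allclose(bm_r2eff(p, nu_grid, CTX8), 12.0, atol=1e-6)

    def test_no_exchange_when_dw_zero(self, nu_grid):
        p = TwoStateParams(0.05, 500.0, 0.0, 12.0)
        np.testing.assert_allclose(bm_r2eff(p, nu_grid, CTX8), 12.0, atol=1e-10)

    def test_matches_brute_force_oracle(self, nu_grid):
        p = TwoStateParams(0.05, 500.0, 3.0, 12.0, )
        assert bm_r2eff(p, 66.7, CTX8) > bm_r2eff(p, 1000.0, CTX8)
        for nu in (nu_grid[0], nu_grid[-1]):
            assert bm_r2eff(p, nu, CTX8) == pytest.approx(
                bm_r2eff_brute(p, nu, CTX8), abs=0.01
            )

    @pytest.mark.parametrize("pb,kex,dw", PARAM_GRID[::7])
    def test_brute_force_agreement_on_grid(self, pb, kex, dw, nu_grid):
        p = TwoStateParams(pb, kex, dw, 12.0)
        for nu in (nu_grid[0], nu_grid[5]):
            assert bm_r2eff(p, nu, CTX6) == pytest.approx(
                bm_r2eff_brute(p, nu, CTX6), abs=0.01
            )

    def test_vectorized_kernel_equals_reference(self, nu_grid):
        n_arr = np.array([n_pulses(0.030, v) for v in nu_grid])
        for pb, kex, dw in PARAM_GRID[::5]:
            p = TwoStateParams(pb, kex, dw, 12.0)
            fast = bm_r2eff_grid(pb, kex, dw_rad_per_s(dw, 800.4), 12.0, 0.030, n_arr)
            np.testing.assert_allclose(fast, bm_r2eff(p, nu_grid, CTX8),
                                       rtol=1e-10, atol=1e-10)

    def test_refocusing_limit_monotone(self, nu_grid):
        for pb, kex, dw in PARAM_GRID[::4]:
            p = TwoStateParams(pb, kex, dw, 12.0)
            curve = np.asarray(bm_r2eff(p, nu_grid, CTX8))
            assert np.all(np.diff(curve) <= 1e-9)
            assert curve[-1] >= 12.0 - 1e-9

    def test_dw_sign_invariance(self, nu_grid):
        n_arr = np.array([n_pulses(0.030, v) for v in nu_grid])
        dw = dw_rad_per_s(3.0, 800.4)
        plus = bm_r2eff_grid(0.05, 500.0, dw, 12.0, 0.030, n_arr)
        minus = bm_r2eff_grid(0.05, 500.0, -dw, 12.0, 0.030, n_arr)
        np.testing.assert_allclose(plus, minus, rtol=1e-12)

    def test_state_label_swap_invariance(self, nu_grid):
        # swapping A and B (populations and shift reference) leaves the
        # observable unchanged
        n_arr = np.array([n_pulses(0.030, v) for v in nu_grid])
        dw = dw_rad_per_s(3.0, 800.4)
        forward = bm_r2eff_grid(0.05, 500.0, dw, 12.0, 0.030, n_arr)
        swapped = bm_r2eff_grid(0.95, 500.0, -dw, 12.0, 0.030, n_arr)
        np.testing.assert_allclose(forward, swapped, rtol=1e-8, atol=1e-8)


class TestCarverRichards:
    def test_fast_exchange_limit(self):
        # in the fast limit the low-nu excess approaches pA pB dw^2 / kex;
        # a long constant-time element is needed to reach genuinely low nu
        # (at T_relax = 30 ms the lowest admissible 66.7 s^-1 still
        # refocuses ~5% of Rex)
        ctx_long = SpectrometerContext(800.4, 298.0, 0.300)
        dw_ppm = 500.0 / (2 * math.pi * 800.4 * 0.10136767)
        p = TwoStateParams(0.05, 5000.0, dw_ppm, 12.0)
        nu_min = admissible_grid(0.300)[0]
        excess = carver_richards_r2eff(p, nu_min, ctx_long) - 12.0
        expected = 0.95 * 0.05 * 500.0**2 / 5000.0
        assert excess == pytest.approx(expected, rel=0.05)
        assert expected == pytest.approx(2.375)

    def test_no_exchange_limit(self, nu_grid):
        p = TwoStateParams(1e-10, 500.0, 3.0, 12.0)
        np.testing.assert_allclose(
            carver_richards_r2eff(p, nu_grid, CTX8), 12.0, atol=1e-5
        )

    def test_agrees_with_numeric_propagator(self, nu_grid):
        p = TwoStateParams(0.03, 1000.0, 2.0, 12.0)
        cr = np.asarray(carver_richards_r2eff(p, nu_grid, CTX6))
        bm = np.asarray(bm_r2eff(p, nu_grid, CTX6))
        np.testing.assert_allclose(cr, bm, rtol=0.02)

    @pytest.mark.parametrize("pb,kex,dw", PARAM_GRID)
    def test_two_percent_validity_envelope(self, pb, kex, dw, nu_grid):
        p = TwoStateParams(pb, kex, dw, 12.0)
        cr = np.asarray(carver_richards_r2eff(p, nu_grid, CTX6))
        bm = np.asarray(bm_r2eff(p, nu_grid, CTX6))
        np.testing.assert_allclose(cr, bm, rtol=0.02)


class TestSimulateSeries:
    def test_noise_free_equals_forward_model(self, nu_grid):
        p = TwoStateParams(0.05, 500.0, 3.0, 12.0)
        sim = simulate_series(p, nu_grid, CTX8, snr=None)
        np.testing.assert_array_equal(sim.r2eff_s1, bm_r2eff(p, nu_grid, CTX8))

    def test_seed_reproducibility(self, nu_grid):
        p = TwoStateParams(0.05, 500.0, 3.0, 12.0)
        a = simulate_series(p, nu_grid, CTX8, snr=50, seed=123)
        b = simulate_series(p, nu_grid, CTX8, snr=50, seed=123)
        np.testing.assert_array_equal(a.r2eff_s1, b.r2eff_s1)

    def test_monte_carlo_sigma(self):
        # 1000 realizations at one frequency: sample SD vs 1/(T_relax*snr)
        p = TwoStateParams(0.05, 500.0, 3.0, 12.0)
        nu = np.array([66.7])
        values = np.array([
            simulate_series(p, nu, CTX8, snr=50, seed=s).r2eff_s1[0]
            for s in range(1000)
        ])
        expected = 1.0 / (0.030 * 50.0)
        assert np.std(values, ddof=1) == pytest.approx(expected, rel=0.05)
        assert expected == pytest.approx(0.667, abs=5e-4)

    def test_sigma_recorded_per_point(self, nu_grid):
        p = TwoStateParams(0.05, 500.0, 3.0, 12.0)
        sim = simulate_series(p, nu_grid, CTX8, snr=80, seed=0)
        np.testing.assert_allclose(sim.sigma_s1, 1.0 / (0.030 * 80.0))

    def test_invalid_snr(self, nu_grid):
        p = TwoStateParams(0.05, 500.0, 3.0, 12.0)
        with pytest.raises(ValueError):
            simulate_series(p, nu_grid, CTX8, snr=-1.0)


class TestAdmissibleGrid:
    def test_endpoints(self):
        grid = admissible_grid(0.030)
        assert grid[0] == pytest.approx(2.0 / 0.030)
        assert grid[-1] == pytest.approx(1000.0)

    def test_all_points_admissible(self):
        for nu in admissible_grid(0.030):
            n_pulses(0.030, nu)  # must not raise

    @settings(max_examples=20, deadline=None)
    @given(t_relax=st.floats(min_value=0.01, max_value=0.5))
    def test_any_constant_time(self, t_relax):
        grid = admissible_grid(t_relax)
        assert len(grid) >= 1
        for nu in grid:
            assert n_pulses(t_relax, nu) % 4 == 0
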