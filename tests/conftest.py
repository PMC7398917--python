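"""Shared fixtures and independent simulation helpers."""

from __future__ import annotations

import numpy as np
import pytest
from scipy.linalg import expm

from relaxdisp.dispersion_core import DispersionSeries
from relaxdisp.exchange_model import (TwoStateParams, admissible_grid,
                                      pulse_train, simulate_series)
from relaxdisp.tables_io import SpectrometerContext

T_RELAX = 0.030
FIELDS = (600.03, 800.4)
TEMPS = (278.0, 283.0, 290.0, 298.0)


@pytest.fixture(scope="session")
def nu_grid():
    return admissible_grid(T_RELAX)


@pytest.fixture
def ctx600():
    return SpectrometerContext(600.03, 298.0, T_RELAX)


@pytest.fixture
def ctx800():
    return SpectrometerContext(800.4, 298.0, T_RELAX)


def make_series(residue_id, p_b, k_ex, dw_ppm, r2inf, field_mhz, temp_k,
                snr=None, seed=0, nu=None):
    """DispersionSeries simulated from the two-state forward model."""
    ctx = SpectrometerContext(field_mhz, temp_k, T_RELAX)
    nu = nu if nu is not None else admissible_grid(T_RELAX)
    sim = simulate_series(
        TwoStateParams(p_b, k_ex, dw_ppm, r2inf), nu, ctx, snr=snr, seed=seed
    )
    return DispersionSeries(residue_id, ctx, sim.nu_cpmg_s1,
                            sim.r2eff_s1, sim.sigma_s1)


def make_flat_series(residue_id, level, field_mhz=800.4, temp_k=298.0,
                     sigma=1e-6, nu=None):
    ctx = SpectrometerContext(field_mhz, temp_k, T_RELAX)
    nu = nu if nu is not None else admissible_grid(T_RELAX)
    return DispersionSeries(residue_id, ctx, np.asarray(nu, dtype=float),
                            np.full(len(nu), float(level)),
                            np.full(len(nu), float(sigma)))


def three_state_r2eff(nu_cpmg, ctx, r2inf, p_b, p_c, kex_ab, kex_ac,
                      dw_b_ppm, dw_c_ppm):
    """Independent 3-state (star topology) CPMG simulator.

    Brute-force propagation with scipy expm; used only as a
    misspecification oracle against the 2-state fitters.
    """
    from relaxdisp.exchange_model import dw_rad_per_s

    p_a = 1.0 - p_b - p_c
    # detailed balance within each A<->X pair
    kab = kex_ab * p_b / (p_a + p_b)
    kba = kex_ab * p_a / (p_a + p_b)
    kac = kex_ac * p_c / (p_a + p_c)
    kca = kex_ac * p_a / (p_a + p_c)
    dwb = dw_rad_per_s(dw_b_ppm, ctx.proton_frequency_MHz)
    dwc = dw_rad_per_s(dw_c_ppm, ctx.proton_frequency_MHz)
    L = np.array(
        [
            [-r2inf - kab - kac, kba, kca],
            [kab, -r2inf - kba + 1j * dwb, 0.0],
            [kac, 0.0, -r2inf - kca + 1j * dwc],
        ],
        dtype=complex,
    )
    out = []
    for nu in np.atleast_1d(nu_cpmg):
        m = np.array([p_a, p_b, p_c], dtype=complex)
        for kind, duration in pulse_train(ctx.t_relax_s, nu):
            if kind == "pulse":
                m = np.conj(m)
            else:
                m = expm(L * duration) @ m
        out.append(-np.log(abs(m.sum())) / ctx.t_relax_s)
    return np.array(out)


def make_three_state_series(residue_id, ctx, nu, snr=50, seed=0, r2inf=13.0):
    """Noisy series from the 3-state oracle with well-separated exchange."""
    clean = three_state_r2eff(nu, ctx, r2inf, p_b=0.06, p_c=0.06,
                              kex_ab=250.0, kex_ac=3500.0,
                              dw_b_ppm=3.5, dw_c_ppm=1.5)
    sigma = 1.0 / (ctx.t_relax_s * snr)
    rng = np.random.default_rng(seed)
    return DispersionSeries(residue_id, ctx, np.asarray(nu, dtype=float),
                            clean + rng.normal(0, sigma, len(clean)),
                            np.full(len(clean), sigma))
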