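import itertools

import numpy as np
import pytest

from relaxdisp.dispersion_fit import (
    DEFAULT_CONFIG,
    FitConfig,
    compare_series,
    fit_global_all,
    fit_global_temperature,
    fit_individual,
    fit_results_table,
    model_select,
)
from relaxdisp.exchange_model import bm_r2eff_grid, dw_rad_per_s, n_pulses
from relaxdisp.thermo_landscape import ThermoEquilibrium, ThermoTransition

from conftest import (
    FIELDS,
    TEMPS,
    make_flat_series,
    make_series,
    make_three_state_series,
)

R2INF = {600.03: 12.0, 800.4: 14.0}
TRUE = dict(p_B=0.05, k_ex=500.0, dw=3.0)


def residue_pair(snr=None, seed=0, **kw):
    true = {**TRUE, **kw}
    return [
        make_series(1, true["p_B"], true["k_ex"], true["dw"], R2INF[f], f, 298.0,
                    snr=snr, seed=seed * 10 + i)
        for i, f in enumerate(FIELDS)
    ]


def thermo_dataset(residue_dws=((1, 3.0), (2, 4.5)), snr=None, seed=0,
                   eq=ThermoEquilibrium(-30.0, -120.0),
                   ts=ThermoTransition(50.0, -40.0)):
    series = []
    k = 0
    for t in TEMPS:
        pb = eq.p_B(t)
        kex = ts.rate(t) / pb
        for rid, dw in residue_dws:
            for f in FIELDS:
                series.append(
                    make_series(rid, pb, kex, dw, R2INF[f], f, t,
                                snr=snr, seed=seed * 1000 + k)
                )
                k += 1
    return series


class TestFitIndividual:
    def test_noise_free_recovery(self):
        res = fit_individual(residue_pair())
        assert res.converged
        assert res.chi2 < 1e-6
        for key, true in TRUE.items():
            assert res.params[key] == pytest.approx(true, rel=0.01)
        for f in FIELDS:
            tag = f"r2inf[1,{f:g}MHz,298K]"
            assert res.params[tag] == pytest.approx(R2INF[f], rel=0.01)

    @pytest.mark.parametrize("pb0,kex0,dw0", list(
        itertools.product((0.01, 0.1), (200.0, 3000.0), (1.0, 6.0))
    ))
    def test_recovery_from_any_grid_start(self, pb0, kex0, dw0):
        cfg = FitConfig(pb_starts=(pb0,), kex_starts=(kex0,), dw_starts=(dw0,),
                        n_optimize=1, max_nfev=1000)
        res = fit_individual(residue_pair(), cfg)
        assert res.chi2 < 1e-6
        assert res.params["p_B"] == pytest.approx(TRUE["p_B"], rel=0.01)

    def test_flat_series_flagged_degenerate(self):
        res = fit_individual(residue_pair(dw=0.0))
        assert res.converged
        # fitted exchange contribution must be negligible: the model curve
        # is flat at r2inf
        n_arr = np.array([n_pulses(0.030, v)
                          for v in residue_pair()[0].nu_cpmg_s1])
        curve = bm_r2eff_grid(
            res.params["p_B"], res.params["k_ex"],
            dw_rad_per_s(res.params["dw"], 800.4),
            res.params["r2inf[1,800.4MHz,298K]"], 0.030, n_arr,
        )
        assert np.ptp(curve) < 0.05

    def test_single_field_warns(self):
        res = fit_individual(residue_pair()[:1])
        assert any("single field" in w for w in res.warnings)

    def test_deterministic(self):
        a = fit_individual(residue_pair(snr=50, seed=3))
        b = fit_individual(residue_pair(snr=50, seed=3))
        assert a.params == b.params
        assert a.chi2 == b.chi2

    def test_mixed_residues_rejected(self):
        series = residue_pair()
        series.append(make_series(2, 0.05, 500.0, 3.0, 14.0, 800.4, 298.0))
        with pytest.raises(ValueError, match="one residue"):
            fit_individual(series)

    def test_uncertainties_calibrate(self):
        # empirical SD of p_B over noisy replicates vs mean reported sigma
        estimates, sigmas = [], []
        for seed in range(40):
            res = fit_individual(residue_pair(snr=50, seed=seed))
            estimates.append(res.params["p_B"])
            sigmas.append(res.errors["p_B"])
        ratio = np.std(estimates, ddof=1) / np.mean(sigmas)
        assert 1.0 / 1.5 < ratio < 1.5


class TestFitGlobalTemperature:
    def test_shared_parameters_recovered(self):
        dws = [(i, dw) for i, dw in enumerate((2.0, 2.8, 3.5, 4.2, 5.0), start=1)]
        series = [
            make_series(rid, 0.05, 800.0, dw, R2INF[f], f, 298.0)
            for rid, dw in dws for f in FIELDS
        ]
        res = fit_global_temperature(series)
        assert res.params["p_B"] == pytest.approx(0.05, rel=0.02)
        assert res.params["k_ex"] == pytest.approx(800.0, rel=0.02)
        for rid, dw in dws:
            assert res.params[f"dw[{rid}]"] == pytest.approx(dw, rel=0.02)

    def test_misspecification_detected(self):
        series = []
        for rid, kex in ((1, 500.0), (2, 2000.0)):
            for f in FIELDS:
                series.append(
                    make_series(rid, 0.05, kex, 3.0, R2INF[f], f, 298.0,
                                snr=100, seed=rid)
                )
        glob = fit_global_temperature(series)
        individual = [
            fit_individual([s for s in series if s.residue_id == rid])
            for rid in (1, 2)
        ]
        assert glob.chi2 > 10.0 * sum(r.chi2 for r in individual)

    def test_single_residue_reduces_to_individual(self):
        series = residue_pair(snr=80, seed=5)
        glob = fit_global_temperature(series)
        ind = fit_individual(series)
        assert glob.chi2 == pytest.approx(ind.chi2, rel=1e-4, abs=1e-8)
        assert glob.params["p_B"] == pytest.approx(ind.params["p_B"], rel=1e-3)

    def test_multiple_temperatures_rejected(self):
        series = [make_series(1, 0.05, 500.0, 3.0, 14.0, 800.4, t) for t in TEMPS]
        with pytest.raises(ValueError, match="one temperature"):
            fit_global_temperature(series)


class TestFitGlobalAll:
    def test_unconstrained_recovers_generating_laws(self):
        eq = ThermoEquilibrium(-30.0, -120.0)
        ts = ThermoTransition(50.0, -40.0)
        res = fit_global_all(thermo_dataset(eq=eq, ts=ts), constrained=False)
        for t in TEMPS:
            assert res.params[f"p_B[{t:g}K]"] == pytest.approx(eq.p_B(t), rel=0.02)
            assert res.params[f"k_ex[{t:g}K]"] == pytest.approx(
                ts.rate(t) / eq.p_B(t), rel=0.02
            )

    def test_constrained_recovers_thermodynamics(self):
        res = fit_global_all(thermo_dataset(), constrained=True)
        assert res.params["dH"] == pytest.approx(-30.0, rel=0.02)
        assert res.params["dS"] == pytest.approx(-120.0, rel=0.02)
        assert res.params["dH_act"] == pytest.approx(50.0, rel=0.02)
        assert res.params["dS_act"] == pytest.approx(-40.0, rel=0.02)

    def test_constrained_has_more_degrees_of_freedom(self):
        data = thermo_dataset(snr=100, seed=2)
        con = fit_global_all(data, constrained=True)
        unc = fit_global_all(data, constrained=False)
        assert con.df > unc.df
        # fewer parameters can never fit better
        assert con.chi2 >= unc.chi2 - 1e-6

    def test_chi2_ordering_across_levels(self):
        data = thermo_dataset(snr=60, seed=9)
        unc = fit_global_all(data, constrained=False)
        individual = [
            fit_individual([s for s in data
                            if s.residue_id == rid
                            and s.context.temperature_K == t])
            for rid in (1, 2) for t in TEMPS
        ]
        assert unc.chi2 >= sum(r.chi2 for r in individual) - 1e-6

    def test_requires_two_temperatures(self):
        with pytest.raises(ValueError, match="2 temperatures"):
            fit_global_all(residue_pair(), constrained=False)


class TestModelSelect:
    def test_perfect_fits_consistent(self):
        data = thermo_dataset()
        ind = [
            fit_individual([s for s in data
                            if s.residue_id == rid
                            and s.context.temperature_K == t])
            for rid in (1, 2) for t in TEMPS
        ]
        glob = fit_global_all(data, constrained=False)
        report = model_select(ind, [glob])
        assert report.attrs["two_state_consistent"]
        assert (report["chi2"] < report["DF"]).all()

    def test_three_state_data_rejected(self, nu_grid, ctx800, ctx600):
        series = [
            make_three_state_series(1, ctx800, nu_grid, snr=50, seed=1),
            make_three_state_series(1, ctx600, nu_grid, snr=50, seed=2),
        ]
        ind = fit_individual(series)
        report = model_select([ind], [ind])
        assert not report.attrs["two_state_consistent"]
        assert ind.chi2 > ind.df

    def test_empty_inputs_rejected(self):
        with pytest.raises(ValueError):
            model_select([], [])


class TestCompareSeries:
    def test_identical_series(self):
        a = residue_pair(snr=50, seed=1)[0]
        chi2, changed = compare_series(a, a)
        assert chi2 == 0.0
        assert not changed

    def test_null_calibration(self):
        # two noise realizations of the same truth: rarely "changed"
        n_changed = 0
        for seed in range(40):
            a = make_series(1, 0.05, 500.0, 3.0, 14.0, 800.4, 298.0,
                            snr=50, seed=2 * seed)
            b = make_series(1, 0.05, 500.0, 3.0, 14.0, 800.4, 298.0,
                            snr=50, seed=2 * seed + 1)
            n_changed += compare_series(a, b)[1]
        assert n_changed <= 2

    def test_quenched_vs_dispersive(self, nu_grid):
        free = make_series(1, 0.05, 500.0, 3.0, 14.0, 800.4, 298.0,
                           snr=50, seed=4)
        bound = make_flat_series(1, 14.0, sigma=1.0 / (0.030 * 50), nu=nu_grid)
        chi2, changed = compare_series(free, bound)
        assert changed

    def test_grid_mismatch(self, nu_grid):
        a = make_series(1, 0.05, 500.0, 3.0, 14.0, 800.4, 298.0)
        b = make_flat_series(1, 14.0, nu=nu_grid[:-1])
        with pytest.raises(ValueError, match="grid"):
            compare_series(a, b)

    def test_residue_mismatch(self):
        a = make_series(1, 0.05, 500.0, 3.0, 14.0, 800.4, 298.0)
        b = make_series(2, 0.05, 500.0, 3.0, 14.0, 800.4, 298.0)
        with pytest.raises(ValueError, match="residue"):
            compare_series(a, b)


def test_fit_results_table_columns():
    res = fit_individual(residue_pair())
    table = fit_results_table([res])
    assert list(table.columns)[:7] == [
        "mode", "pB", "pB_err", "kex", "kex_err", "dw_ppm", "chi2"
    ]
    assert table.loc[0, "pB"] == pytest.approx(0.05, rel=0.01)
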