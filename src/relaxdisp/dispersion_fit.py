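"""Two-state fitting of dispersion series at four levels, plus model checks.

Levels: per-residue (individual), global per temperature, global across
all temperatures without constraints, and global with van't Hoff /
Eyring temperature laws generating p_B(T) and k_ex(T) from four
thermodynamic parameters.  All fits minimize the sigma-weighted chi^2
against the numerical Bloch-McConnell forward model with multi-start
least squares; model selection compares chi^2 against degrees of
freedom exactly as stated for each level.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import least_squares

from .constants import K_B, PLANCK_H, R_GAS
from .dispersion_core import DispersionSeries
from .exchange_model import bm_r2eff_grid, dw_rad_per_s, n_pulses

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class FitConfig:
    """Multi-start grid, bounds and optimizer policy (all reproducible)."""

    pb_starts: tuple[float, ...] = (0.01, 0.05, 0.1)
    kex_starts: tuple[float, ...] = (200.0, 1000.0, 3000.0)
    dw_starts: tuple[float, ...] = (1.0, 3.0, 6.0)
    pb_bounds: tuple[float, float] = (1e-4, 0.5)
    kex_bounds: tuple[float, float] = (10.0, 1e5)
    dw_bounds: tuple[float, float] = (0.05, 15.0)
    r2inf_bounds: tuple[float, float] = (0.1, 200.0)
    dh_bounds: tuple[float, float] = (-300.0, 300.0)     # kJ/mol
    ds_bounds: tuple[float, float] = (-1000.0, 1000.0)   # J/(mol K)
    n_optimize: int = 3          # starts fully optimized after chi^2 screening
    early_stop_chi2: float = 1e-8  # stop once a start essentially nails the data
    max_nfev: int = 400
    xtol: float = 1e-10
    ftol: float = 1e-10


DEFAULT_CONFIG = FitConfig()


@dataclass(frozen=True)
class FitResult:
    mode: str
    params: dict[str, float]
    errors: dict[str, float]
    chi2: float
    df: int
    n_points: int
    converged: bool
    n_restarts_used: int
    warnings: tuple[str, ...] = ()

    @property
    def reduced_chi2(self) -> float:
        return self.chi2 / self.df


# ---------------------------------------------------------------------------
# series bookkeeping
# ---------------------------------------------------------------------------

def _series_key(s: DispersionSeries) -> tuple[int, float, float]:
    return (s.residue_id, s.context.temperature_K, s.context.proton_frequency_MHz)


def _series_tag(s: DispersionSeries) -> str:
    return f"{s.residue_id},{s.context.proton_frequency_MHz:g}MHz,{s.context.temperature_K:g}K"


class _Problem:
    """Maps a flat parameter vector to per-series two-state curves.

    ``plan`` is a list of callables, one per series, turning the theta
    vector into (p_B, k_ex, dw_rad, r2inf).
    """

    def __init__(self, series_list: list[DispersionSeries], names, lower, upper, plan,
                 extra_residuals=None):
        self.series = series_list
        self.names = list(names)
        self.lower = np.asarray(lower, dtype=float)
        self.upper = np.asarray(upper, dtype=float)
        self.plan = plan
        self.extra_residuals = extra_residuals
        self.n_arrs = [
            np.array([n_pulses(s.context.t_relax_s, v) for v in s.nu_cpmg_s1])
            for s in series_list
        ]
        self.n_points = sum(len(s) for s in series_list)

    def residuals(self, theta: np.ndarray, with_extra: bool = True) -> np.ndarray:
        out = []
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            for s, n_arr, mapper in zip(self.series, self.n_arrs, self.plan):
                pb, kex, dw_rad, r2inf = mapper(theta)
                model = bm_r2eff_grid(pb, kex, dw_rad, r2inf,
                                      s.context.t_relax_s, n_arr)
                out.append((model - s.r2eff_s1) / s.sigma_s1)
        if with_extra and self.extra_residuals is not None:
            out.append(np.atleast_1d(self.extra_residuals(theta)))
        res = np.concatenate(out)
        return np.nan_to_num(res, nan=1e8, posinf=1e8, neginf=-1e8)

    def chi2(self, theta: np.ndarray) -> float:
        """Data-only chi^2 (any soft-constraint penalty rows excluded)."""
        r = self.residuals(theta, with_extra=False)
        return float(r @ r)


def _data_r2inf_guess(s: DispersionSeries, cfg: FitConfig) -> float:
    tail = float(np.mean(s.r2eff_s1[-min(3, len(s)):]))
    return min(max(tail, cfg.r2inf_bounds[0] + 1e-3), cfg.r2inf_bounds[1] - 1e-3)


def _run_multistart(problem: _Problem, starts: list[np.ndarray], cfg: FitConfig):
    """Screen starts by raw chi^2, optimize the best few, keep the winner."""
    scores = []
    for th in starts:
        try:
            scores.append(problem.chi2(th))
        except (ArithmeticError, FloatingPointError):
            scores.append(np.inf)
    order = np.argsort(scores, kind="stable")

    best = None
    n_used = 0
    for idx in order[: max(1, cfg.n_optimize)]:
        n_used += 1
        sol = least_squares(
            problem.residuals,
            np.clip(starts[idx], problem.lower, problem.upper),
            bounds=(problem.lower, problem.upper),
            method="trf",
            x_scale="jac",
            max_nfev=cfg.max_nfev,
            xtol=cfg.xtol,
            ftol=cfg.ftol,
        )
        # rank by the full cost (incl. any penalty rows) so that a
        # penalized mirror-branch solution never beats a clean one
        key = 2.0 * sol.cost
        if best is None or key < best[0]:
            best = (key, problem.chi2(sol.x), sol)
        if key < cfg.early_stop_chi2:
            break
    return best[1], best[2], n_used


def _errors_from_jacobian(sol, names) -> tuple[dict[str, float], list[str]]:
    warn: list[str] = []
    jtj = sol.jac.T @ sol.jac
    try:
        cov = np.linalg.inv(jtj)
        diag = np.diag(cov)
        if np.any(diag < 0):
            raise np.linalg.LinAlgError
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(jtj)
        diag = np.abs(np.diag(cov))
        warn.append("singular Jacobian: parameter errors from pseudo-inverse")
    errs = {n: float(math.sqrt(max(d, 0.0))) for n, d in zip(names, diag)}
    return errs, warn


def _finish(problem: _Problem, mode: str, chi2: float, sol, n_used: int,
            extra_warnings: list[str]) -> FitResult:
    errors, warn = _errors_from_jacobian(sol, problem.names)
    params = dict(zip(problem.names, (float(v) for v in sol.x)))
    df = problem.n_points - len(problem.names)
    if df < 1:
        raise ValueError("fewer data points than free parameters")
    warn = extra_warnings + warn
    # non-identifiability heuristics
    for name, value in params.items():
        if name.startswith("dw") and value <= problem.lower[problem.names.index(name)] * 1.01:
            warn.append(f"{name} at lower bound: exchange amplitude not identifiable")
    return FitResult(
        mode=mode,
        params=params,
        errors=errors,
        chi2=float(chi2),
        df=df,
        n_points=problem.n_points,
        converged=bool(sol.success and np.isfinite(chi2)),
        n_restarts_used=n_used,
        warnings=tuple(warn),
    )


# ---------------------------------------------------------------------------
# fit modes
# ---------------------------------------------------------------------------

def fit_individual(series_list: list[DispersionSeries],
                   config: FitConfig = DEFAULT_CONFIG) -> FitResult:
    """Fit one residue at one temperature: shared (p_B, k_ex, dw), r2inf per field."""
    residues = {s.residue_id for s in series_list}
    temps = {s.context.temperature_K for s in series_list}
    if len(residues) != 1 or len(temps) != 1:
        raise ValueError("fit_individual takes one residue at one temperature")
    warn = []
    if len(series_list) < 2:
        warn.append("single field: exchange parameters may be poorly determined")
    if sum(len(s) for s in series_list) <= 5:
        raise ValueError("need more than 5 points in total")

    names = ["p_B", "k_ex", "dw"]
    lower = [config.pb_bounds[0], config.kex_bounds[0], config.dw_bounds[0]]
    upper = [config.pb_bounds[1], config.kex_bounds[1], config.dw_bounds[1]]
    for s in series_list:
        names.append(f"r2inf[{_series_tag(s)}]")
        lower.append(config.r2inf_bounds[0])
        upper.append(config.r2inf_bounds[1])

    freqs = [s.context.proton_frequency_MHz for s in series_list]

    def make_mapper(i, f):
        return lambda th: (th[0], th[1], dw_rad_per_s(th[2], f), th[3 + i])

    plan = [make_mapper(i, f) for i, f in enumerate(freqs)]
    problem = _Problem(series_list, names, lower, upper, plan)

    r2inf_guesses = [_data_r2inf_guess(s, config) for s in series_list]
    starts = [
        np.array([pb, kex, dw] + r2inf_guesses)
        for pb in config.pb_starts
        for kex in config.kex_starts
        for dw in config.dw_starts
    ]
    chi2, sol, n_used = _run_multistart(problem, starts, config)
    return _finish(problem, "individual", chi2, sol, n_used, warn)


def fit_global_temperature(series_list: list[DispersionSeries],
                           config: FitConfig = DEFAULT_CONFIG) -> FitResult:
    """Global fit at one temperature: shared (p_B, k_ex), dw per residue."""
    temps = {s.context.temperature_K for s in series_list}
    if len(temps) != 1:
        raise ValueError("fit_global_temperature takes one temperature")
    residues = sorted({s.residue_id for s in series_list})

    names = ["p_B", "k_ex"]
    lower = [config.pb_bounds[0], config.kex_bounds[0]]
    upper = [config.pb_bounds[1], config.kex_bounds[1]]
    dw_index = {}
    for r in residues:
        dw_index[r] = len(names)
        names.append(f"dw[{r}]")
        lower.append(config.dw_bounds[0])
        upper.append(config.dw_bounds[1])
    r2_index = {}
    for s in series_list:
        r2_index[_series_key(s)] = len(names)
        names.append(f"r2inf[{_series_tag(s)}]")
        lower.append(config.r2inf_bounds[0])
        upper.append(config.r2inf_bounds[1])

    def make_mapper(s):
        i_dw = dw_index[s.residue_id]
        i_r2 = r2_index[_series_key(s)]
        f = s.context.proton_frequency_MHz
        return lambda th: (th[0], th[1], dw_rad_per_s(th[i_dw], f), th[i_r2])

    problem = _Problem(series_list, names, lower, upper,
                       [make_mapper(s) for s in series_list])

    base = np.empty(len(names))
    for s in series_list:
        base[r2_index[_series_key(s)]] = _data_r2inf_guess(s, config)
    starts = []
    for pb in config.pb_starts:
        for kex in config.kex_starts:
            for dw in config.dw_starts:
                th = base.copy()
                th[0], th[1] = pb, kex
                for r in residues:
                    th[dw_index[r]] = dw
                starts.append(th)
    chi2, sol, n_used = _run_multistart(problem, starts, config)
    return _finish(problem, "global_T", chi2, sol, n_used, [])


def _thermo_pb_kex(dh, ds, dha, dsa, t_k):
    """(p_B, k_ex) at one temperature from the 4 thermodynamic parameters.

    Exponents and the resulting k_ex are clamped so that absurd trial
    steps of the optimizer produce large-but-finite residuals instead
    of overflow.
    """
    keq = math.exp(min(max(-(dh * 1000.0 - t_k * ds) / (R_GAS * t_k), -500.0), 500.0))
    pb = keq / (1.0 + keq)
    pb = min(max(pb, 1e-12), 1.0 - 1e-12)
    exponent = min(max(-(dha * 1000.0 - t_k * dsa) / (R_GAS * t_k), -500.0), 40.0)
    kab = (K_B * t_k / PLANCK_H) * math.exp(exponent)
    return pb, min(kab / pb, 1e6)


def fit_global_all(series_list: list[DispersionSeries], constrained: bool = False,
                   config: FitConfig = DEFAULT_CONFIG) -> FitResult:
    """Global fit across temperatures; dw shared across T per residue.

    Unconstrained: free (p_B, k_ex) per temperature.  Constrained:
    p_B(T) from the van't Hoff law and k_AB(T) from the Eyring law,
    leaving four thermodynamic parameters (dH, dS, dH_act, dS_act).
    """
    temps = sorted({s.context.temperature_K for s in series_list})
    if len(temps) < 2:
        raise ValueError("need >= 2 temperatures for an all-temperature fit")
    residues = sorted({s.residue_id for s in series_list})

    names: list[str] = []
    lower: list[float] = []
    upper: list[float] = []
    if constrained:
        names = ["dH", "dS", "dH_act", "dS_act"]
        lower = [config.dh_bounds[0], config.ds_bounds[0],
                 config.dh_bounds[0], config.ds_bounds[0]]
        upper = [config.dh_bounds[1], config.ds_bounds[1],
                 config.dh_bounds[1], config.ds_bounds[1]]
        pbkex_index = None
    else:
        pbkex_index = {}
        for t in temps:
            pbkex_index[t] = len(names)
            names += [f"p_B[{t:g}K]", f"k_ex[{t:g}K]"]
            lower += [config.pb_bounds[0], config.kex_bounds[0]]
            upper += [config.pb_bounds[1], config.kex_bounds[1]]

    dw_index = {}
    for r in residues:
        dw_index[r] = len(names)
        names.append(f"dw[{r}]")
        lower.append(config.dw_bounds[0])
        upper.append(config.dw_bounds[1])
    r2_index = {}
    for s in series_list:
        r2_index[_series_key(s)] = len(names)
        names.append(f"r2inf[{_series_tag(s)}]")
        lower.append(config.r2inf_bounds[0])
        upper.append(config.r2inf_bounds[1])

    def make_mapper(s):
        i_dw = dw_index[s.residue_id]
        i_r2 = r2_index[_series_key(s)]
        f = s.context.proton_frequency_MHz
        t_k = s.context.temperature_K
        if constrained:
            def mapper(th):
                pb, kex = _thermo_pb_kex(th[0], th[1], th[2], th[3], t_k)
                return pb, kex, dw_rad_per_s(th[i_dw], f), th[i_r2]
        else:
            i_pb = pbkex_index[t_k]
            def mapper(th):
                return th[i_pb], th[i_pb + 1], dw_rad_per_s(th[i_dw], f), th[i_r2]
        return mapper

    extra = None
    if constrained:
        t_arr = np.asarray(temps)

        def extra(th):
            # soft hinge keeping the B state minor (K(T) <= 1) at every
            # data temperature: the label-swapped branch fits equally
            # well and must be excluded by parameterization
            lnk = -(th[0] * 1000.0 - t_arr * th[1]) / (R_GAS * t_arr)
            return 50.0 * np.maximum(0.0, lnk)

    problem = _Problem(series_list, names, lower, upper,
                       [make_mapper(s) for s in series_list],
                       extra_residuals=extra)

    base = np.empty(len(names))
    for s in series_list:
        base[r2_index[_series_key(s)]] = _data_r2inf_guess(s, config)

    warn: list[str] = []
    if constrained:
        # seed from the unconstrained fit's per-temperature (p_B, k_ex)
        from .thermo_landscape import eyring_fit, vant_hoff_fit

        starts = []
        try:
            un = fit_global_all(series_list, constrained=False, config=config)
            pb_t = [(t, un.params[f"p_B[{t:g}K]"], None) for t in temps]
            kab_t = [
                (t, un.params[f"p_B[{t:g}K]"] * un.params[f"k_ex[{t:g}K]"], None)
                for t in temps
            ]
            eq = vant_hoff_fit(pb_t)
            ts = eyring_fit(kab_t)
            th = base.copy()
            th[0], th[1] = eq.dH_kJmol, eq.dS_JmolK
            th[2], th[3] = ts.dH_act_kJmol, ts.dS_act_JmolK
            for r in residues:
                th[dw_index[r]] = un.params[f"dw[{r}]"]
            starts.append(th)
        except (ValueError, RuntimeError) as exc:
            warn.append(f"unconstrained seeding failed ({exc}); grid starts only")
        for dh, dha in ((-30.0, 50.0), (-10.0, 70.0), (20.0, 40.0)):
            th = base.copy()
            th[0], th[1], th[2], th[3] = dh, -100.0, dha, -30.0
            for r in residues:
                th[dw_index[r]] = config.dw_starts[1]
            starts.append(th)
        mode = "constrained"
    else:
        starts = []
        for pb in config.pb_starts:
            for kex in config.kex_starts:
                for dw in config.dw_starts:
                    th = base.copy()
                    for t in temps:
                        th[pbkex_index[t]] = pb
                        th[pbkex_index[t] + 1] = kex
                    for r in residues:
                        th[dw_index[r]] = dw
                    starts.append(th)
        mode = "global_all"

    chi2, sol, n_used = _run_multistart(problem, starts, config)
    result = _finish(problem, mode, chi2, sol, n_used, warn)
    if constrained:
        # report the implied per-temperature populations and rates too
        extra = dict(result.params)
        for t in temps:
            pb, kex = _thermo_pb_kex(result.params["dH"], result.params["dS"],
                                     result.params["dH_act"], result.params["dS_act"], t)
            if not 0.0 < pb < 1.0:
                raise ValueError(f"constrained fit maps p_B({t} K) outside (0, 1)")
            extra[f"p_B[{t:g}K]"] = pb
            extra[f"k_ex[{t:g}K]"] = kex
        result = replace(result, params=extra)
    return result


# ---------------------------------------------------------------------------
# model selection and series comparison
# ---------------------------------------------------------------------------

def model_select(individual_results: list[FitResult],
                 global_results: list[FitResult]) -> pd.DataFrame:
    """chi^2-vs-DF consistency report across fit levels.

    Verdict "two-state consistent" requires chi^2 < DF for every global
    fit and sum(chi^2) < sum(DF) over the individual fits.
    """
    if not individual_results or not global_results:
        raise ValueError("need results at both levels")
    n_ind = sum(r.n_points for r in individual_results)
    for g in global_results:
        if g.n_points != n_ind and g.mode in ("global_T",):
            pass  # a per-temperature global sees a subset; checked by caller
    rows = []
    chi2_ind = sum(r.chi2 for r in individual_results)
    df_ind = sum(r.df for r in individual_results)
    rows.append(("individual (sum)", chi2_ind, df_ind, chi2_ind < df_ind))
    for g in global_results:
        rows.append((g.mode, g.chi2, g.df, g.chi2 < g.df))
    consistent = all(r[3] for r in rows)
    report = pd.DataFrame(rows, columns=["level", "chi2", "DF", "chi2_lt_DF"])
    report.attrs["two_state_consistent"] = bool(consistent)
    return report


def compare_series(a: DispersionSeries, b: DispersionSeries,
                   threshold: float = 2.0) -> tuple[float, bool]:
    """Mean per-point chi^2 between two series on the same grid.

    Returns (chi2 per point, changed).  Used both for the
    concentration-dependence control and for quench/gain comparisons.
    """
    if a.residue_id != b.residue_id:
        raise ValueError("series are for different residues")
    if len(a) != len(b) or not np.allclose(a.nu_cpmg_s1, b.nu_cpmg_s1, rtol=1e-9):
        raise ValueError("nu_cpmg grids differ; no interpolation is performed")
    num = (np.asarray(a.r2eff_s1) - np.asarray(b.r2eff_s1)) ** 2
    den = np.asarray(a.sigma_s1) ** 2 + np.asarray(b.sigma_s1) ** 2
    chi2_per_point = float(np.mean(num / den))
    return chi2_per_point, chi2_per_point > threshold


def fit_results_table(results: list[FitResult]) -> pd.DataFrame:
    """Flatten FitResults into a report table (one row per fit)."""
    rows = []
    for r in results:
        row = {
            "mode": r.mode,
            "pB": r.params.get("p_B", np.nan),
            "pB_err": r.errors.get("p_B", np.nan),
            "kex": r.params.get("k_ex", np.nan),
            "kex_err": r.errors.get("k_ex", np.nan),
            "dw_ppm": r.params.get("dw", np.nan),
            "chi2": r.chi2,
            "DF": r.df,
            "converged": r.converged,
        }
        rows.append(row)
    return pd.DataFrame(rows)
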