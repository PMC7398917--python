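"""Generators for every input table the pipeline consumes.

The default design mirrors the acquisition the analysis expects: two
fields (600.03 and 800.4 MHz 1H), four temperatures (278, 283, 290,
298 K), a 30 ms constant-time CPMG element, and intensity noise set by
a signal-to-noise ratio.  Each generator returns (or writes) tables in
exactly the schema of :mod:`relaxdisp.tables_io`, together with a truth
record for recovery scoring.  Identical seeds give identical output.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .dispersion_core import Regime
from .exchange_model import TwoStateParams, admissible_grid, bm_r2eff
from .relaxometry import rigid_rates
from .tables_io import SpectrometerContext
from .thermo_landscape import ThermoEquilibrium, ThermoTransition

DEFAULT_FIELDS_MHZ = (600.03, 800.4)
DEFAULT_TEMPS_K = (278.0, 283.0, 290.0, 298.0)
DEFAULT_T_RELAX_S = 0.030


@dataclass(frozen=True)
class SyntheticTruth:
    """Ground truth behind one generated dispersion dataset."""

    regimes: dict[int, Regime]
    dw_ppm: dict[int, float]              # per dispersive residue
    equilibrium: ThermoEquilibrium
    transition: ThermoTransition          # A -> ts (forward, k_AB)
    r2inf_s1: dict[float, float]          # per field (proton MHz)
    fast_rex_s1: float                    # elevation of fast-regime residues
    tau_c_ns: float
    seed: int

    def p_B(self, T_K: float) -> float:
        return self.equilibrium.p_B(T_K)

    def k_ex(self, T_K: float) -> float:
        return self.transition.rate(T_K) / self.equilibrium.p_B(T_K)


def default_truth(seed: int = 0,
                  n_dispersive: int = 5,
                  n_fast: int = 5,
                  n_flat: int = 10,
                  dH_kJmol: float = -30.0,
                  dS_JmolK: float = -120.0,
                  dH_act_kJmol: float = 50.0,
                  dS_act_JmolK: float = -40.0,
                  tau_c_ns: float = 6.5) -> SyntheticTruth:
    """A paper-like truth: thermally activated two-state minor state."""
    rng = np.random.default_rng(seed)
    regimes: dict[int, Regime] = {}
    dw: dict[int, float] = {}
    rid = 1
    for _ in range(n_dispersive):
        regimes[rid] = Regime.DISPERSIVE
        dw[rid] = float(rng.uniform(2.0, 5.0))
        rid += 1
    for _ in range(n_fast):
        regimes[rid] = Regime.FAST
        rid += 1
    for _ in range(n_flat):
        regimes[rid] = Regime.NO_EXCHANGE
        rid += 1
    return SyntheticTruth(
        regimes=regimes,
        dw_ppm=dw,
        equilibrium=ThermoEquilibrium(dH_kJmol=dH_kJmol, dS_JmolK=dS_JmolK),
        transition=ThermoTransition(dH_act_kJmol=dH_act_kJmol,
                                    dS_act_JmolK=dS_act_JmolK),
        r2inf_s1={600.03: 11.0, 800.4: 14.0},
        fast_rex_s1=5.0,
        tau_c_ns=tau_c_ns,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# relaxation rates
# ---------------------------------------------------------------------------

def gen_rigid_relaxation(
    tau_c_ns: float,
    proton_frequency_MHz: float,
    n_residues: int = 20,
    noise_frac: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Rigid-rotor R1/R2/NOE table (residue, R1, R1_err, ... schema).

    Multiplicative Gaussian noise of fractional width ``noise_frac``;
    reported errors equal the noise level (floored at a tiny value so
    noise-free tables still validate).
    """
    r1, r2, noe = rigid_rates(tau_c_ns, proton_frequency_MHz)
    rng = np.random.default_rng(seed)
    rows = []
    err_floor = 1e-6
    for rid in range(1, n_residues + 1):
        scale = 1.0 + (rng.normal(0.0, noise_frac, size=3) if noise_frac > 0
                       else np.zeros(3))
        rows.append(
            {
                "residue": rid,
                "R1": r1 * scale[0],
                "R1_err": max(abs(r1 * noise_frac), err_floor),
                "R2": r2 * scale[1],
                "R2_err": max(abs(r2 * noise_frac), err_floor),
                "NOE": noe * scale[2],
                "NOE_err": max(abs(noe * noise_frac), err_floor),
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# dispersion intensities
# ---------------------------------------------------------------------------

def default_contexts(condition_label: str = "free") -> list[SpectrometerContext]:
    return [
        SpectrometerContext(
            proton_frequency_MHz=f, temperature_K=t,
            t_relax_s=DEFAULT_T_RELAX_S, condition_label=condition_label,
        )
        for t in DEFAULT_TEMPS_K
        for f in DEFAULT_FIELDS_MHZ
    ]


def gen_dispersion_dataset(
    truth: SyntheticTruth,
    contexts: list[SpectrometerContext] | None = None,
    nu_grid=None,
    snr: float | None = 150.0,
    seed: int | None = None,
    i0: float = 1e6,
) -> dict[SpectrometerContext, pd.DataFrame]:
    """Intensity tables (one per context) following the truth record.

    Dispersive residues follow the two-state forward model with p_B(T)
    and k_ex(T) from the truth's van't Hoff/Eyring laws; fast residues
    are flat at r2inf + Rex; no-exchange residues flat at r2inf.
    Intensities are I = I0 exp(-R2eff T_relax) plus Gaussian noise of
    sigma_I = I0/snr, so the downstream error propagation is exercised.
    """
    contexts = contexts if contexts is not None else default_contexts()
    rng = np.random.default_rng(truth.seed if seed is None else seed)
    out: dict[SpectrometerContext, pd.DataFrame] = {}
    for ctx in contexts:
        nu = (np.asarray(nu_grid, dtype=float) if nu_grid is not None
              else admissible_grid(ctx.t_relax_s))
        r2inf = truth.r2inf_s1[ctx.proton_frequency_MHz]
        sigma_i = 0.0 if snr is None else i0 / snr
        noise_col = max(sigma_i, i0 * 1e-9)
        rows = []
        for rid, regime in sorted(truth.regimes.items()):
            if regime is Regime.DISPERSIVE:
                params = TwoStateParams(
                    p_B=truth.p_B(ctx.temperature_K),
                    k_ex_s1=truth.k_ex(ctx.temperature_K),
                    dw_ppm=truth.dw_ppm[rid],
                    r2inf_s1=r2inf,
                )
                r2eff = np.asarray(bm_r2eff(params, nu, ctx))
            elif regime is Regime.FAST:
                r2eff = np.full_like(nu, r2inf + truth.fast_rex_s1)
            else:
                r2eff = np.full_like(nu, r2inf)

            intensities = i0 * np.exp(-r2eff * ctx.t_relax_s)
            ref = i0
            if sigma_i > 0:
                intensities = intensities + rng.normal(0, sigma_i, size=len(nu))
                ref = i0 + rng.normal(0, sigma_i)
            rows.append({"residue": rid, "nu_cpmg": 0.0,
                         "intensity": ref, "noise": noise_col})
            for v, inten in zip(nu, intensities):
                rows.append({"residue": rid, "nu_cpmg": v,
                             "intensity": inten, "noise": noise_col})
        out[ctx] = pd.DataFrame(rows)
    return out


# ---------------------------------------------------------------------------
# chemical shifts
# ---------------------------------------------------------------------------

def gen_csp_dataset(
    n_residues: int = 50,
    hotspots: tuple[int, ...] = (11, 24, 36),
    effect_ppm: float = 0.2,
    noise_ppm: float = 0.002,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame, dict]:
    """(free table, bound table, truth) for a titration CSP analysis.

    Hotspot residues get a perturbation of magnitude ``effect_ppm``
    split between 1H and 15N; every residue's bound shifts carry
    Gaussian referencing noise of ``noise_ppm``.
    """
    bad = [h for h in hotspots if not 1 <= h <= n_residues]
    if bad:
        raise ValueError(f"hotspot ids outside residue range: {bad}")
    rng = np.random.default_rng(seed)
    resid = np.arange(1, n_residues + 1)
    d_h = rng.uniform(7.5, 9.5, size=n_residues)
    d_n = rng.uniform(105.0, 130.0, size=n_residues)
    free = pd.DataFrame({"residue": resid, "delta_H": d_h, "delta_N": d_n})

    bh = d_h.copy()
    bn = d_n.copy()
    if noise_ppm > 0:
        bh = bh + rng.normal(0, noise_ppm, size=n_residues)
        bn = bn + rng.normal(0, 10 * noise_ppm, size=n_residues)
    for h in hotspots:
        eps = rng.uniform(0.0, 1.0)
        bh[h - 1] += effect_ppm
        bn[h - 1] += 10.0 * effect_ppm * eps
    bound = pd.DataFrame({"residue": resid, "delta_H": bh, "delta_N": bn})
    return free, bound, {"hotspots": tuple(hotspots), "seed": seed}


def gen_shifts_by_temperature(
    slopes_ppb_per_K: dict[int, float],
    temps_K=DEFAULT_TEMPS_K,
    noise_ppm: float = 0.0,
    seed: int = 0,
) -> pd.DataFrame:
    """Long table (residue, temperature_K, delta_H) for dd/dT analysis."""
    rng = np.random.default_rng(seed)
    rows = []
    for rid, slope in sorted(slopes_ppb_per_K.items()):
        intercept = rng.uniform(7.5, 9.5)
        for t in temps_K:
            d = intercept + slope * 1e-3 * (t - temps_K[0])
            if noise_ppm > 0:
                d += rng.normal(0, noise_ppm)
            rows.append({"residue": rid, "temperature_K": t, "delta_H": d})
    return pd.DataFrame(rows)


def write_dataset(tables: dict[SpectrometerContext, pd.DataFrame], outdir) -> list[Path]:
    """Write one TSV per context with context columns included."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for ctx, df in tables.items():
        df = df.copy()
        df["proton_frequency_MHz"] = ctx.proton_frequency_MHz
        df["temperature_K"] = ctx.temperature_K
        df["t_relax_s"] = ctx.t_relax_s
        df["condition"] = ctx.condition_label
        name = (f"intensities_{ctx.condition_label}_"
                f"{ctx.proton_frequency_MHz:g}MHz_{ctx.temperature_K:g}K.tsv")
        path = outdir / name
        df.to_csv(path, sep="\t", index=False, float_format="%.17g")
        paths.append(path)
    return paths
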