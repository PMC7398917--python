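"""15N spin-relaxation summaries: R2/R1 exchange flagging and tau_c.

Residues whose R2/R1 ratio exceeds the mean plus one standard deviation
(computed over the rigid subset, hetNOE > 0.65) are flagged as being in
conformational exchange.  The overall rotational correlation time is
obtained by numerically inverting the rigid-rotor (order parameter 1)
R2/R1 curve at the trimmed-mean ratio of the rigid residues.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import brentq
from scipy.stats import trim_mean

from .constants import (
    DELTA_SIGMA_N,
    GAMMA_H,
    GAMMA_N,
    MU_0,
    NU_N_OVER_NU_H,
    PLANCK_H,
    R_NH,
)
from .tables_io import SpectrometerContext

logger = logging.getLogger(__name__)

HETNOE_RIGID_MIN = 0.65  # flexible tails excluded from summary statistics


@dataclass(frozen=True)
class RelaxationRecord:
    """Per-residue R1, R2 and heteronuclear NOE with errors."""

    residue_id: int
    context: SpectrometerContext
    R1_s1: float
    R1_err_s1: float
    R2_s1: float
    R2_err_s1: float
    hetNOE: float
    hetNOE_err: float
    residue_code: str = ""

    def __post_init__(self) -> None:
        if self.R1_s1 <= 0 or self.R2_s1 <= 0:
            raise ValueError(
                f"residue {self.residue_id}: R1 and R2 must be positive "
                f"(R1 = {self.R1_s1}, R2 = {self.R2_s1})"
            )
        if self.R1_err_s1 <= 0 or self.R2_err_s1 <= 0 or self.hetNOE_err <= 0:
            raise ValueError(f"residue {self.residue_id}: errors must be positive")

    @property
    def ratio(self) -> float:
        return self.R2_s1 / self.R1_s1


@dataclass(frozen=True)
class TauCEstimate:
    tau_c_ns: float
    n_residues_used: int
    ratio_used: float

    def __post_init__(self) -> None:
        if not self.tau_c_ns > 0:
            raise ValueError("tau_c must be positive")


# ---------------------------------------------------------------------------
# rigid-rotor rates (isotropic tumbling, order parameter 1)
# ---------------------------------------------------------------------------

def _spectral_density(omega: float, tau_c_s: float) -> float:
    """Lorentzian J(w) = (2/5) tau_c / (1 + (w tau_c)^2)."""
    return 0.4 * tau_c_s / (1.0 + (omega * tau_c_s) ** 2)


def _interaction_constants(proton_frequency_MHz: float) -> tuple[float, float, float, float]:
    """(d, c, omega_H, omega_N): dipolar/CSA constants and Larmor frequencies."""
    omega_h = 2.0 * math.pi * proton_frequency_MHz * 1e6
    omega_n = omega_h * NU_N_OVER_NU_H  # magnitude
    d = MU_0 * PLANCK_H * GAMMA_H * abs(GAMMA_N) / (8.0 * math.pi**2 * R_NH**3)
    c = omega_n * abs(DELTA_SIGMA_N) * 1e-6 / math.sqrt(3.0)
    return d, c, omega_h, omega_n


def rigid_rates(tau_c_ns: float, proton_frequency_MHz: float) -> tuple[float, float, float]:
    """(R1, R2, hetNOE) of a rigid isotropic rotor at the given field.

    Standard dipolar + CSA expressions with r_NH = 1.02 A and a 15N CSA
    of -160 ppm; the negative nitrogen gyromagnetic ratio enters the NOE
    through the gamma_H/gamma_N factor.
    """
    if tau_c_ns <= 0:
        raise ValueError("tau_c must be positive")
    tau = tau_c_ns * 1e-9
    d, c, wh, wn = _interaction_constants(proton_frequency_MHz)

    j0 = _spectral_density(0.0, tau)
    jn = _spectral_density(wn, tau)
    jh = _spectral_density(wh, tau)
    jdiff = _spectral_density(wh - wn, tau)
    jsum = _spectral_density(wh + wn, tau)

    r1 = (d**2 / 4.0) * (jdiff + 3.0 * jn + 6.0 * jsum) + c**2 * jn
    r2 = (d**2 / 8.0) * (4.0 * j0 + jdiff + 3.0 * jn + 6.0 * jh + 6.0 * jsum) \
        + (c**2 / 6.0) * (4.0 * j0 + 3.0 * jn)
    noe = 1.0 + (d**2 / (4.0 * r1)) * (GAMMA_H / GAMMA_N) * (6.0 * jsum - jdiff)
    return r1, r2, noe


def rigid_r2_over_r1(tau_c_ns: float, proton_frequency_MHz: float) -> float:
    """Rigid-rotor R2/R1; tends to 1 in extreme narrowing, grows with tau_c."""
    r1, r2, _ = rigid_rates(tau_c_ns, proton_frequency_MHz)
    return r2 / r1


# ---------------------------------------------------------------------------
# flagging and tau_c estimation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RatioFlags:
    residue_ids: np.ndarray
    ratios: np.ndarray
    flagged: np.ndarray
    mean: float
    sd: float


def r2_over_r1_flags(records: list[RelaxationRecord]) -> RatioFlags:
    """Per-residue R2/R1 with exchange flags (ratio > mean + 1 SD).

    Mean and SD are taken over residues with hetNOE above 0.65 so that
    flexible termini do not deflate the baseline.
    """
    if len(records) < 5:
        raise ValueError("need >= 5 relaxation records")
    qualifying = [r for r in records if r.hetNOE > HETNOE_RIGID_MIN]
    if len(qualifying) < 5:
        raise ValueError(
            f"only {len(qualifying)} residues with hetNOE > {HETNOE_RIGID_MIN}; "
            "need >= 5 for summary statistics"
        )
    ratios_q = np.array([r.ratio for r in qualifying])
    mean = float(np.mean(ratios_q))
    sd = float(np.std(ratios_q, ddof=1))

    ids = np.array([r.residue_id for r in records])
    ratios = np.array([r.ratio for r in records])
    flagged = ratios > mean + sd
    return RatioFlags(ids, ratios, flagged, mean, sd)


def _tau_c_seed_ns(ratio: float, proton_frequency_MHz: float) -> float:
    """Closed-form seed tau_c ~ sqrt(6 R2/R1 - 7) / (4 pi nu_N)."""
    nu_n_hz = proton_frequency_MHz * 1e6 * NU_N_OVER_NU_H
    arg = 6.0 * ratio - 7.0
    if arg <= 0:
        return 1.0
    return 1e9 * math.sqrt(arg) / (4.0 * math.pi * nu_n_hz)


def estimate_tc(
    records: list[RelaxationRecord],
    proton_frequency_MHz: float,
    tau_range_ns: tuple[float, float] = (0.5, 50.0),
    trim: float = 0.1,
) -> TauCEstimate:
    """Rotational correlation time from the rigid-residue R2/R1 ratio.

    The rigid subset is unflagged residues with hetNOE > 0.65; its
    trimmed-mean ratio is inverted through the rigid-rotor curve by
    1-D root finding to 1e-4 ns.
    """
    flags = r2_over_r1_flags(records)
    rigid = [
        r for r, f in zip(records, flags.flagged)
        if not f and r.hetNOE > HETNOE_RIGID_MIN
    ]
    if not rigid:
        logger.warning("no unflagged rigid residues; falling back to all residues")
        rigid = list(records)
    ratios = np.array([r.ratio for r in rigid])
    ratio = float(trim_mean(ratios, trim)) if len(ratios) >= 5 else float(np.mean(ratios))

    lo, hi = tau_range_ns
    f = lambda tc: rigid_r2_over_r1(tc, proton_frequency_MHz) - ratio
    if f(lo) > 0 or f(hi) < 0:
        # the ratio curve has a shallow minimum near ~0.1 ns; a ratio below
        # the bracket cannot be inverted
        raise ValueError(
            f"R2/R1 = {ratio:.3f} not attainable for tau_c in "
            f"[{lo}, {hi}] ns at {proton_frequency_MHz} MHz"
        )
    seed = min(max(_tau_c_seed_ns(ratio, proton_frequency_MHz), lo), hi)
    # seed brackets a tight interval when possible, else the full range
    a, b = lo, hi
    if f(seed) > 0 and seed > lo:
        b = seed
    elif f(seed) < 0 and seed < hi:
        a = seed
    tau = brentq(f, a, b, xtol=1e-4)
    return TauCEstimate(
        tau_c_ns=float(tau),
        n_residues_used=len(rigid),
        ratio_used=ratio,
    )
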