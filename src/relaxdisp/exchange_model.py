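"""Forward model of relaxation-compensated CPMG under two-state exchange.

The ground-truth observable is computed by propagating the transverse
magnetization of the A/B spin ensemble through the explicit pulse train
with exact piecewise matrix exponentials of the 2x2 Bloch-McConnell
generator; ideal 180 degree pulses act as complex conjugation.  The
Carver-Richards closed form is provided as an independent cross-check.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .constants import NU_N_OVER_NU_H
from .tables_io import SpectrometerContext


class PulseTrainError(ValueError):
    """Requested CPMG frequency does not fit the relaxation-compensated train."""


@dataclass(frozen=True)
class TwoStateParams:
    """Two-state exchange parameter set: A (major) <-> B (minor).

    ``r2inf_s1`` is the shared intrinsic transverse rate of both states
    for one (field, temperature) series.
    """

    p_B: float
    k_ex_s1: float
    dw_ppm: float
    r2inf_s1: float

    def __post_init__(self) -> None:
        if not 0.0 < self.p_B <= 0.5:
            raise ValueError(f"p_B must be in (0, 0.5], got {self.p_B}")
        if not self.k_ex_s1 > 0:
            raise ValueError("k_ex must be positive")
        if self.dw_ppm < 0:
            raise ValueError("dw_ppm must be >= 0")
        if not self.r2inf_s1 > 0:
            raise ValueError("r2inf must be positive")

    @property
    def p_A(self) -> float:
        return 1.0 - self.p_B

    @property
    def k_AB_s1(self) -> float:
        return self.p_B * self.k_ex_s1

    @property
    def k_BA_s1(self) -> float:
        return (1.0 - self.p_B) * self.k_ex_s1


def dw_rad_per_s(dw_ppm: float, proton_frequency_MHz: float) -> float:
    """Convert a 15N shift difference from ppm to rad/s at the given field."""
    return 2.0 * math.pi * dw_ppm * proton_frequency_MHz * NU_N_OVER_NU_H


# ---------------------------------------------------------------------------
# pulse train
# ---------------------------------------------------------------------------

def n_pulses(t_relax_s: float, nu_cpmg_s1: float, rel_tol: float = 5e-3) -> int:
    """Number of 180 pulses for the constant-time train, or raise.

    N = 2 * T_relax * nu_cpmg must be (within printing tolerance) an
    integer divisible by 4.
    """
    n_exact = 2.0 * t_relax_s * nu_cpmg_s1
    n = int(round(n_exact))
    if n <= 0 or abs(n_exact - n) > rel_tol * max(n_exact, 1.0) or n % 4 != 0:
        lower = max(4, 4 * (n // 4))
        candidates = sorted({max(4, lower - 4), lower, lower + 4})
        nearest = ", ".join(f"{c / (2.0 * t_relax_s):.1f}" for c in candidates)
        raise PulseTrainError(
            f"nu_cpmg = {nu_cpmg_s1} s^-1 gives N = {n_exact:.3f} pulses; "
            f"N must be a positive integer divisible by 4. "
            f"Nearest admissible frequencies: {nearest} s^-1"
        )
    return n


def pulse_train(t_relax_s: float, nu_cpmg_s1: float) -> list[tuple[str, float]]:
    """Event list of the relaxation-compensated CPMG element.

    Returns ``[("delay", d/2), ("pulse", 0), ("delay", d), ...]`` with N
    ideal 180 pulses and total delay time exactly ``t_relax_s``.
    """
    n = n_pulses(t_relax_s, nu_cpmg_s1)
    delta = t_relax_s / n  # == 1/(2 nu) up to printing tolerance
    events: list[tuple[str, float]] = [("delay", delta / 2.0)]
    for i in range(n):
        events.append(("pulse", 0.0))
        events.append(("delay", delta if i < n - 1 else delta / 2.0))
    return events


# ---------------------------------------------------------------------------
# Bloch-McConnell propagation
# ---------------------------------------------------------------------------

def _generator(params: TwoStateParams, dw_rad: float) -> np.ndarray:
    """2x2 evolution generator in the rotating frame of state A."""
    kab, kba, r2 = params.k_AB_s1, params.k_BA_s1, params.r2inf_s1
    return np.array(
        [
            [-r2 - kab, kba],
            [kab, -r2 - kba + 1j * dw_rad],
        ],
        dtype=complex,
    )


def _expm2(mat: np.ndarray, t: float) -> np.ndarray:
    """exp(mat * t) for a 2x2 complex matrix via closed-form eigenvalues."""
    a, b = mat[0, 0], mat[0, 1]
    c, d = mat[1, 0], mat[1, 1]
    tr = a + d
    disc = np.sqrt((a - d) ** 2 + 4.0 * b * c + 0j)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    e1, e2 = np.exp(l1 * t), np.exp(l2 * t)
    if abs(l1 - l2) < 1e-12 * max(1.0, abs(l1)):
        # degenerate pair: exp(Mt) = e^{l t} (I + t (M - l I))
        ident = np.eye(2, dtype=complex)
        return e1 * (ident + t * (mat - l1 * ident))
    f1 = (e1 - e2) / (l1 - l2)
    f0 = e1 - l1 * f1
    return f0 * np.eye(2, dtype=complex) + f1 * mat


def _train_propagator(E_half: np.ndarray, E_full: np.ndarray, n: int) -> np.ndarray:
    """Linear propagator of the N-pulse train with conjugation pulses folded in.

    For even N the antilinear conjugations pair up and the full train
    reduces to  E_half . (conj(E) E)^{(N-2)/2} . conj(E) . E_half.
    """
    assert n % 2 == 0
    core = np.conj(E_full) @ E_full
    return E_half @ np.linalg.matrix_power(core, (n - 2) // 2) @ np.conj(E_full) @ E_half


def bm_r2eff(
    params: TwoStateParams,
    nu_cpmg_s1,
    context: SpectrometerContext,
) -> float | np.ndarray:
    """R2eff from exact Bloch-McConnell propagation through the pulse train.

    Accepts a scalar frequency or an array; vectorized over the grid.
    """
    nu = np.atleast_1d(np.asarray(nu_cpmg_s1, dtype=float))
    dw_rad = dw_rad_per_s(params.dw_ppm, context.proton_frequency_MHz)
    L = _generator(params, dw_rad)
    m0 = np.array([params.p_A, params.p_B], dtype=complex)
    s0 = abs(m0.sum())
    t = context.t_relax_s

    out = np.empty(nu.shape, dtype=float)
    for i, v in enumerate(nu):
        n = n_pulses(t, v)
        delta = t / n
        E_full = _expm2(L, delta)
        E_half = _expm2(L, delta / 2.0)
        mT = _train_propagator(E_half, E_full, n) @ m0
        ratio = abs(mT.sum()) / s0
        if not np.isfinite(ratio) or ratio <= 0:
            raise ArithmeticError(
                f"non-finite magnetization at nu_cpmg = {v}: ratio = {ratio}"
            )
        out[i] = -math.log(ratio) / t
    return out if np.ndim(nu_cpmg_s1) else float(out[0])


def bm_r2eff_brute(
    params: TwoStateParams,
    nu_cpmg_s1: float,
    context: SpectrometerContext,
    max_step_s: float = 1e-6,
) -> float:
    """Brute-force oracle: piecewise-exponential propagation in fine steps.

    Each delay is subdivided into equal steps no longer than
    ``max_step_s``; deliberately independent of the production path
    (no train-propagator algebra, no matrix powers).
    """
    dw_rad = dw_rad_per_s(params.dw_ppm, context.proton_frequency_MHz)
    L = _generator(params, dw_rad)
    m = np.array([params.p_A, params.p_B], dtype=complex)
    s0 = abs(m.sum())
    for kind, duration in pulse_train(context.t_relax_s, nu_cpmg_s1):
        if kind == "pulse":
            m = np.conj(m)
        else:
            n_sub = max(1, int(math.ceil(duration / max_step_s)))
            E = _expm2(L, duration / n_sub)
            for _ in range(n_sub):
                m = E @ m
    return -math.log(abs(m.sum()) / s0) / context.t_relax_s


def bm_r2eff_grid(
    p_B: float,
    k_ex_s1: float,
    dw_rad: float,
    r2inf_s1: float,
    t_relax_s: float,
    n_pulse_arr: np.ndarray,
) -> np.ndarray:
    """Vectorized Bloch-McConnell R2eff over a grid of pulse counts.

    Same physics as :func:`bm_r2eff` but evaluated with closed-form 2x2
    eigen-algebra across the whole nu grid at once; this is the hot path
    of the least-squares fitters.  ``n_pulse_arr`` holds the (validated)
    pulse counts N for each grid point.
    """
    n_arr = np.asarray(n_pulse_arr, dtype=float)
    kab = p_B * k_ex_s1
    kba = (1.0 - p_B) * k_ex_s1
    a = -r2inf_s1 - kab
    b = kba
    c = kab
    d = -r2inf_s1 - kba + 1j * dw_rad

    tr = a + d
    disc = np.sqrt((a - d) ** 2 + 4.0 * b * c + 0j)
    l1 = 0.5 * (tr + disc)
    l2 = 0.5 * (tr - disc)
    degenerate_l = abs(l1 - l2) < 1e-12 * max(1.0, abs(l1))

    def _exp_elements(t: np.ndarray):
        """E(t) = f0 I + f1 L, elementwise over the vector of times t."""
        e1 = np.exp(l1 * t)
        if degenerate_l:
            f1 = t * e1
            f0 = (1.0 - l1 * t) * e1
        else:
            e2 = np.exp(l2 * t)
            f1 = (e1 - e2) / (l1 - l2)
            f0 = e1 - l1 * f1
        return (f0 + f1 * a, f1 * b, f1 * c, f0 + f1 * d)

    delta = t_relax_s / n_arr
    E = _exp_elements(delta)
    H = _exp_elements(delta / 2.0)
    Ec = tuple(np.conj(x) for x in E)

    def _mm(x, y):
        """(2x2)@(2x2) with elementwise (vectorized) entries."""
        return (
            x[0] * y[0] + x[1] * y[2],
            x[0] * y[1] + x[1] * y[3],
            x[2] * y[0] + x[3] * y[2],
            x[2] * y[1] + x[3] * y[3],
        )

    # core C = conj(E) E, raised to the (N-2)/2 power via its eigenpair
    C = _mm(Ec, E)
    k = ((n_arr - 2.0) / 2.0)
    trc = C[0] + C[3]
    detc = C[0] * C[3] - C[1] * C[2]
    dsc = np.sqrt(trc**2 - 4.0 * detc + 0j)
    m1 = 0.5 * (trc + dsc)
    m2 = 0.5 * (trc - dsc)
    sep = np.abs(m1 - m2)
    ok = sep > 1e-12 * np.maximum(1.0, np.abs(m1))
    safe_den = np.where(ok, m1 - m2, 1.0)
    p1 = np.power(m1, k)
    p2 = np.power(m2, k)
    g1 = (p1 - p2) / safe_den          # C^k = g0 I + g1 C
    g0 = p1 - m1 * g1
    g1 = np.where(ok, g1, k * np.power(m1, k - 1.0))
    g0 = np.where(ok, g0, (1.0 - k) * np.power(m1, k))
    Ck = (g0 + g1 * C[0], g1 * C[1], g1 * C[2], g0 + g1 * C[3])

    P = _mm(H, _mm(Ck, _mm(Ec, H)))
    pa, pb = 1.0 - p_B, p_B
    mT_sum = (P[0] + P[2]) * pa + (P[1] + P[3]) * pb
    ratio = np.abs(mT_sum)  # |m0_A + m0_B| = 1
    return -np.log(ratio) / t_relax_s


# ---------------------------------------------------------------------------
# Carver-Richards closed form
# ---------------------------------------------------------------------------

def carver_richards_r2eff(
    params: TwoStateParams,
    nu_cpmg_s1,
    context: SpectrometerContext,
) -> float | np.ndarray:
    """Carver-Richards approximation (equal intrinsic rates in A and B).

    Documented validity: agrees with :func:`bm_r2eff` to within 2% of
    the exchange contribution for p_B <= 0.15.
    """
    nu = np.atleast_1d(np.asarray(nu_cpmg_s1, dtype=float))
    for v in nu:
        n_pulses(context.t_relax_s, v)
    dw = dw_rad_per_s(params.dw_ppm, context.proton_frequency_MHz)
    pa, pb, kex = params.p_A, params.p_B, params.k_ex_s1

    psi = kex**2 - dw**2
    zeta = -2.0 * dw * kex * (pa - pb)
    root = np.sqrt(psi**2 + zeta**2)
    with np.errstate(invalid="ignore"):
        eta_p = np.sqrt(np.maximum(psi + root, 0.0) / 2.0) / (2.0 * nu)
        eta_m = np.sqrt(np.maximum(-psi + root, 0.0) / 2.0) / (2.0 * nu)
    d_p = 0.5 * (1.0 + (psi + 2.0 * dw**2) / root) if root > 0 else 1.0
    d_m = 0.5 * (-1.0 + (psi + 2.0 * dw**2) / root) if root > 0 else 0.0

    arg = d_p * np.cosh(eta_p) - d_m * np.cos(eta_m)
    out = params.r2inf_s1 + 0.5 * kex - nu * np.arccosh(np.maximum(arg, 1.0))
    return out if np.ndim(nu_cpmg_s1) else float(out[0])


# ---------------------------------------------------------------------------
# simulation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SimulatedSeries:
    """Thin container for a simulated dispersion series (see dispersion_core
    for the pipeline-facing DispersionSeries; this avoids an import cycle)."""

    nu_cpmg_s1: np.ndarray
    r2eff_s1: np.ndarray
    sigma_s1: np.ndarray


def simulate_series(
    params: TwoStateParams,
    nu_grid,
    context: SpectrometerContext,
    snr: float | None = None,
    seed: int | None = None,
) -> SimulatedSeries:
    """Forward-simulate one dispersion series, optionally with noise.

    With a finite SNR, Gaussian noise of sigma = 1/(T_relax * snr) is
    added to R2eff and the same sigma is recorded per point; with
    ``snr=None`` points equal :func:`bm_r2eff` exactly and sigma is a
    nominal tiny value.
    """
    nu = np.asarray(nu_grid, dtype=float)
    clean = np.asarray(bm_r2eff(params, nu, context), dtype=float)
    if snr is None:
        return SimulatedSeries(nu, clean, np.full_like(clean, 1e-6))
    if not snr > 0:
        raise ValueError("snr must be positive or None")
    sigma = 1.0 / (context.t_relax_s * snr)
    rng = np.random.default_rng(seed)
    noisy = clean + rng.normal(0.0, sigma, size=clean.shape)
    return SimulatedSeries(nu, noisy, np.full_like(clean, sigma))


def admissible_grid(t_relax_s: float, n_points: int = 11,
                    nu_max_s1: float = 1000.0) -> np.ndarray:
    """Evenly spread admissible CPMG frequencies from the minimum (N=4) up."""
    n_max = max(4, int(2.0 * t_relax_s * nu_max_s1 + 1e-9) // 4 * 4)
    admissible = np.arange(4, n_max + 1, 4)
    idx = np.unique(np.round(np.linspace(0, len(admissible) - 1,
                                         min(n_points, len(admissible)))).astype(int))
    return admissible[idx] / (2.0 * t_relax_s)
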