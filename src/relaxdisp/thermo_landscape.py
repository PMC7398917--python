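"""Equilibrium and transition-state thermodynamics from T-dependent fits.

van't Hoff: ln K vs 1/T with K = p_B/(1 - p_B), slope -dH/R and
intercept dS/R.  Eyring: ln(k h / (k_B T)) vs 1/T, slope -dH_act/R and
intercept dS_act/R.  Both are weighted linear regressions in the
linearized variables with delta-method weights; with exactly two
temperatures the line is exactly determined and flagged as having no
redundancy.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np

from .constants import K_B, PLANCK_H, R_GAS

logger = logging.getLogger(__name__)

T_MIN_K = 250.0  # Celsius-range inputs are a unit error, reject


@dataclass(frozen=True)
class ThermoEquilibrium:
    """dH (kJ/mol) and dS (J/(mol K)) of the A <-> B equilibrium."""

    dH_kJmol: float
    dS_JmolK: float
    dH_err_kJmol: float = float("nan")
    dS_err_JmolK: float = float("nan")
    exactly_determined: bool = False

    def dG_kJmol(self, T_K: float) -> float:
        return self.dH_kJmol - T_K * self.dS_JmolK / 1000.0

    def equilibrium_constant(self, T_K: float) -> float:
        return math.exp(-self.dG_kJmol(T_K) * 1000.0 / (R_GAS * T_K))

    def p_B(self, T_K: float) -> float:
        k = self.equilibrium_constant(T_K)
        return k / (1.0 + k)


@dataclass(frozen=True)
class ThermoTransition:
    """Activation dH (kJ/mol) and dS (J/(mol K)) of a barrier crossing."""

    dH_act_kJmol: float
    dS_act_JmolK: float
    dH_act_err_kJmol: float = float("nan")
    dS_act_err_JmolK: float = float("nan")
    exactly_determined: bool = False

    def dG_act_kJmol(self, T_K: float) -> float:
        return self.dH_act_kJmol - T_K * self.dS_act_JmolK / 1000.0

    def rate(self, T_K: float) -> float:
        return (K_B * T_K / PLANCK_H) * math.exp(
            -self.dG_act_kJmol(T_K) * 1000.0 / (R_GAS * T_K)
        )


def _check_temperatures(t_arr: np.ndarray) -> None:
    if len(t_arr) < 2:
        raise ValueError("need at least 2 temperatures")
    if np.any(t_arr < T_MIN_K):
        raise ValueError(
            f"temperature below {T_MIN_K} K: inputs must be Kelvin, not Celsius"
        )
    if len(np.unique(t_arr)) != len(t_arr):
        raise ValueError("duplicate temperatures")


def _weighted_line(x: np.ndarray, y: np.ndarray, sigma_y: np.ndarray | None):
    """Weighted least-squares line; returns (slope, intercept, err_s, err_i).

    Errors are from the weighted normal-equation covariance; NaN for an
    exactly determined two-point fit.
    """
    n = len(x)
    if sigma_y is None or np.any(~np.isfinite(sigma_y)) or np.any(sigma_y <= 0):
        w = np.ones(n)
    else:
        w = 1.0 / sigma_y**2
    X = np.column_stack([x, np.ones(n)])
    A = X.T @ (w[:, None] * X)
    b = X.T @ (w * y)
    coef = np.linalg.solve(A, b)
    if n == 2:
        return coef[0], coef[1], float("nan"), float("nan")
    cov = np.linalg.inv(A)
    return coef[0], coef[1], math.sqrt(cov[0, 0]), math.sqrt(cov[1, 1])


def vant_hoff_fit(pB_by_T: list[tuple[float, float, float | None]]) -> ThermoEquilibrium:
    """Fit minor-state populations vs temperature to the van't Hoff line.

    ``pB_by_T`` rows are (T_K, p_B, sigma_pB); sigma may be None for an
    unweighted fit.  sigma(ln K) = sigma_pB / (p_B (1 - p_B)).
    """
    t = np.array([row[0] for row in pB_by_T], dtype=float)
    pb = np.array([row[1] for row in pB_by_T], dtype=float)
    sig = np.array(
        [row[2] if len(row) > 2 and row[2] is not None else np.nan for row in pB_by_T],
        dtype=float,
    )
    _check_temperatures(t)
    if np.any((pb <= 0) | (pb >= 1)):
        raise ValueError("p_B must lie strictly inside (0, 1)")

    lnk = np.log(pb / (1.0 - pb))
    sigma_lnk = None if np.any(~np.isfinite(sig)) else sig / (pb * (1.0 - pb))
    slope, intercept, s_err, i_err = _weighted_line(1.0 / t, lnk, sigma_lnk)
    if len(t) == 2:
        logger.warning("van't Hoff fit with 2 points: exactly determined, no redundancy")
    return ThermoEquilibrium(
        dH_kJmol=-slope * R_GAS / 1000.0,
        dS_JmolK=intercept * R_GAS,
        dH_err_kJmol=s_err * R_GAS / 1000.0,
        dS_err_JmolK=i_err * R_GAS,
        exactly_determined=len(t) == 2,
    )


def eyring_fit(k_by_T: list[tuple[float, float, float | None]]) -> ThermoTransition:
    """Fit rate constants vs temperature to the Eyring line.

    ``k_by_T`` rows are (T_K, k_s1, sigma_k); transmission coefficient 1.
    """
    t = np.array([row[0] for row in k_by_T], dtype=float)
    k = np.array([row[1] for row in k_by_T], dtype=float)
    sig = np.array(
        [row[2] if len(row) > 2 and row[2] is not None else np.nan for row in k_by_T],
        dtype=float,
    )
    _check_temperatures(t)
    if np.any(k <= 0):
        raise ValueError("rates must be positive")

    y = np.log(k * PLANCK_H / (K_B * t))
    sigma_y = None if np.any(~np.isfinite(sig)) else sig / k
    slope, intercept, s_err, i_err = _weighted_line(1.0 / t, y, sigma_y)
    if len(t) == 2:
        logger.warning("Eyring fit with 2 points: exactly determined, no redundancy")
    return ThermoTransition(
        dH_act_kJmol=-slope * R_GAS / 1000.0,
        dS_act_JmolK=intercept * R_GAS,
        dH_act_err_kJmol=s_err * R_GAS / 1000.0,
        dS_act_err_JmolK=i_err * R_GAS,
        exactly_determined=len(t) == 2,
    )


def landscape_table(
    eq: ThermoEquilibrium, ts: ThermoTransition, T_K: float
):
    """Free-energy landscape rows (dG, dH, -T dS) at one temperature.

    Rows: the A -> B equilibrium, the A -> transition-state barrier, and
    the derived B -> transition-state barrier, which enforces
    dG_act(A->ts) - dG_act(B->ts) = dG(A->B) exactly.
    """
    import pandas as pd

    if T_K < T_MIN_K:
        raise ValueError("temperature must be Kelvin")

    rows = []
    dh_eq, ds_eq = eq.dH_kJmol, eq.dS_JmolK
    rows.append(("A->B equilibrium", eq.dG_kJmol(T_K), dh_eq, -T_K * ds_eq / 1000.0))
    dh_a, ds_a = ts.dH_act_kJmol, ts.dS_act_JmolK
    rows.append(("A->ts barrier", ts.dG_act_kJmol(T_K), dh_a, -T_K * ds_a / 1000.0))
    # reverse barrier derived by thermodynamic closure
    dh_b = dh_a - dh_eq
    ds_b = ds_a - ds_eq
    rows.append(
        ("B->ts barrier", dh_b - T_K * ds_b / 1000.0, dh_b, -T_K * ds_b / 1000.0)
    )
    return pd.DataFrame(
        rows, columns=["leg", "dG_kJmol", "dH_kJmol", "minus_TdS_kJmol"]
    )
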