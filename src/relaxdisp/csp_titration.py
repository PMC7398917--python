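"""Chemical-shift perturbations and amide temperature coefficients."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .tables_io import ShiftRecord


@dataclass(frozen=True)
class CSPRecord:
    residue_id: int
    csp_ppm: float
    delta_H_ppm: float
    delta_N_ppm: float
    significant: bool = False

    def __post_init__(self) -> None:
        if self.csp_ppm < 0:
            raise ValueError("csp must be non-negative")


@dataclass(frozen=True)
class TempCoefficient:
    residue_id: int
    slope_ppb_per_K: float
    intercept_ppm: float
    r_squared: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.r_squared <= 1.0 + 1e-12:
            raise ValueError("r_squared must lie in [0, 1]")


def compute_csp(free: ShiftRecord, bound: ShiftRecord) -> CSPRecord:
    """Combined 1H/15N perturbation: sqrt(0.5 dH^2 + 0.5 (dN/10)^2)."""
    if free.residue_id != bound.residue_id:
        raise ValueError(
            f"residue mismatch: {free.residue_id} vs {bound.residue_id}"
        )
    d_h = bound.delta_H_ppm - free.delta_H_ppm
    d_n = bound.delta_N_ppm - free.delta_N_ppm
    csp = math.sqrt(0.5 * d_h**2 + 0.5 * (d_n / 10.0) ** 2)
    return CSPRecord(
        residue_id=free.residue_id, csp_ppm=csp,
        delta_H_ppm=d_h, delta_N_ppm=d_n,
    )


def compute_csp_set(
    free: list[ShiftRecord], bound: list[ShiftRecord]
) -> list[CSPRecord]:
    """Pair two shift tables by residue and compute all CSPs."""
    bound_by_id = {r.residue_id: r for r in bound}
    out = []
    for rec in free:
        if rec.residue_id in bound_by_id:
            out.append(compute_csp(rec, bound_by_id[rec.residue_id]))
    return out


def label_significant(
    csps: list[CSPRecord], n_sd: float = 2.0
) -> tuple[list[CSPRecord], float, float, float]:
    """Flag CSPs above mean + n_sd * SD; returns (records, mean, sd, threshold)."""
    if len(csps) < 5:
        raise ValueError("need >= 5 residues to set a significance threshold")
    values = np.array([c.csp_ppm for c in csps])
    mean = float(np.mean(values))
    sd = float(np.std(values, ddof=1))
    threshold = mean + n_sd * sd
    flagged = [
        CSPRecord(
            residue_id=c.residue_id, csp_ppm=c.csp_ppm,
            delta_H_ppm=c.delta_H_ppm, delta_N_ppm=c.delta_N_ppm,
            significant=bool(c.csp_ppm > threshold),
        )
        for c in csps
    ]
    return flagged, mean, sd, threshold


def temp_coefficient(
    shifts_by_T: list[tuple[float, float]], residue_id: int = -1
) -> TempCoefficient:
    """Amide-proton temperature coefficient dd_HN/dT in ppb/K.

    Ordinary least squares of delta_HN (ppm) against T (K); a constant
    series has slope 0 and, by convention, r^2 = 1 (the line explains
    all of the zero variance).
    """
    t = np.array([row[0] for row in shifts_by_T], dtype=float)
    d = np.array([row[1] for row in shifts_by_T], dtype=float)
    if len(t) < 2:
        raise ValueError("need at least 2 temperatures")
    if len(np.unique(t)) != len(t):
        raise ValueError("duplicate temperatures")

    slope, intercept = np.polyfit(t, d, 1)
    pred = slope * t + intercept
    ss_tot = float(np.sum((d - np.mean(d)) ** 2))
    ss_res = float(np.sum((d - pred) ** 2))
    r2 = 1.0 if ss_tot == 0.0 else 1.0 - ss_res / ss_tot
    return TempCoefficient(
        residue_id=residue_id,
        slope_ppb_per_K=float(slope) * 1000.0,
        intercept_ppm=float(intercept),
        r_squared=max(0.0, min(1.0, r2)),
    )
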