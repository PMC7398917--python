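"""From peak intensities to R2eff series, baseline estimation and regime calls.

R2eff(nu_CPMG) = -(1/T_relax) ln(I/I0) with error 1/(T_relax * SNR),
SNR = I/noise.  The exchange-free baseline R2eff_inf for a context is a
robust (median/MAD, iteratively trimmed) location of the per-residue
mean R2eff; each residue is then labelled no_exchange, fast (flat but
elevated) or dispersive (significant amplitude).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from enum import Enum

import numpy as np

from .tables_io import IntensityRecord, SpectrometerContext

logger = logging.getLogger(__name__)

MAD_TO_SD = 1.4826  # consistency factor: MAD -> SD for a Gaussian


class Regime(str, Enum):
    NO_EXCHANGE = "no_exchange"
    FAST = "fast"
    DISPERSIVE = "dispersive"


@dataclass(frozen=True)
class DispersionSeries:
    """One residue's R2eff(nu_CPMG) curve with per-point errors."""

    residue_id: int
    context: SpectrometerContext
    nu_cpmg_s1: np.ndarray
    r2eff_s1: np.ndarray
    sigma_s1: np.ndarray

    def __post_init__(self) -> None:
        nu = np.asarray(self.nu_cpmg_s1, dtype=float)
        if nu.ndim != 1 or not (len(nu) == len(self.r2eff_s1) == len(self.sigma_s1)):
            raise ValueError("nu, r2eff and sigma must be 1-D and equal length")
        if np.any(np.diff(nu) <= 0):
            raise ValueError("nu_cpmg must be strictly increasing")
        if np.any(np.asarray(self.sigma_s1) <= 0):
            raise ValueError("all sigma must be positive")

    def __len__(self) -> int:
        return len(self.nu_cpmg_s1)

    @property
    def fittable(self) -> bool:
        return len(self) >= 4


@dataclass(frozen=True)
class BaselineEstimate:
    """Exchange-free R2eff level for one (field, temperature, condition)."""

    context: SpectrometerContext
    r2inf_s1: float
    spread_s1: float
    n_supporting_residues: int

    def __post_init__(self) -> None:
        if not self.r2inf_s1 > 0:
            raise ValueError("r2inf must be positive")


@dataclass(frozen=True)
class RegimeLabel:
    residue_id: int
    context: SpectrometerContext
    label: Regime
    mean_elevation_s1: float
    amplitude_s1: float
    amplitude_z: float
    elevation_z: float


def compute_r2eff(
    intensity: float, intensity_ref: float, t_relax_s: float, noise: float
) -> tuple[float, float]:
    """Effective transverse rate and its error from one peak intensity.

    r2eff = -(1/T_relax) ln(I/I0);  sigma = 1/(T_relax * SNR), SNR = I/noise.
    r2eff may come out negative when noise puts I above I0.
    """
    if intensity <= 0 or intensity_ref <= 0:
        raise ValueError(
            f"non-positive intensity (I = {intensity}, I0 = {intensity_ref}): "
            "peak vanished; drop the point"
        )
    if t_relax_s <= 0 or noise <= 0:
        raise ValueError("t_relax and noise must be positive")
    r2eff = -math.log(intensity / intensity_ref) / t_relax_s
    sigma = noise / (t_relax_s * intensity)
    return r2eff, sigma


def build_series(
    records: list[IntensityRecord], context: SpectrometerContext
) -> DispersionSeries:
    """Assemble a DispersionSeries from one residue's intensity group.

    Duplicate nu_CPMG rows are averaged (noise combined in quadrature)
    with a warning; points whose peak vanished are dropped with a warning.
    """
    refs = [r for r in records if r.is_reference]
    if len(refs) != 1:
        raise ValueError(
            f"group must contain exactly one reference record, found {len(refs)}"
        )
    ref = refs[0]
    if ref.intensity <= 0:
        raise ValueError(
            f"residue {ref.residue_id}: reference intensity "
            f"{ref.intensity} is not positive"
        )

    by_nu: dict[float, list[IntensityRecord]] = {}
    for rec in records:
        if not rec.is_reference:
            by_nu.setdefault(rec.nu_cpmg_s1, []).append(rec)

    nus, r2effs, sigmas = [], [], []
    for nu in sorted(by_nu):
        group = by_nu[nu]
        if len(group) > 1:
            logger.warning(
                "residue %d: %d duplicate rows at nu_cpmg = %g; averaging",
                ref.residue_id, len(group), nu,
            )
        intensity = float(np.mean([g.intensity for g in group]))
        # quadrature combination of the noise of averaged replicates
        noise = float(np.sqrt(np.sum(np.square([g.noise for g in group])))) / len(group)
        try:
            r2eff, sigma = compute_r2eff(
                intensity, ref.intensity, context.t_relax_s, noise
            )
        except ValueError as exc:
            logger.warning("residue %d: dropping point: %s", ref.residue_id, exc)
            continue
        nus.append(nu)
        r2effs.append(r2eff)
        sigmas.append(sigma)

    return DispersionSeries(
        residue_id=ref.residue_id,
        context=context,
        nu_cpmg_s1=np.array(nus),
        r2eff_s1=np.array(r2effs),
        sigma_s1=np.array(sigmas),
    )


def estimate_baseline(
    series_set: list[DispersionSeries],
    k_flag: float = 2.0,
    max_iter: int = 10,
) -> BaselineEstimate:
    """Robust exchange-free baseline from a context's full series set.

    Iterates: baseline = median of per-residue mean R2eff; residues with
    mean above median + 1.4826*MAD*k_flag are excluded; repeat until the
    surviving set is stable.  Exchanging residues only shift R2eff up,
    hence the one-sided trim.
    """
    if len(series_set) < 5:
        raise ValueError(f"need >= 5 series to estimate a baseline, got {len(series_set)}")
    contexts = {s.context for s in series_set}
    if len(contexts) > 1:
        raise ValueError("all series must share one context")

    means = np.array([float(np.mean(s.r2eff_s1)) for s in series_set])
    keep = np.ones(len(means), dtype=bool)
    for _ in range(max_iter):
        if not keep.any():
            raise RuntimeError("baseline estimation excluded every residue")
        med = float(np.median(means[keep]))
        mad = float(np.median(np.abs(means[keep] - med)))
        new_keep = means <= med + MAD_TO_SD * mad * k_flag
        if not new_keep.any():
            break  # keep last stable subset
        if np.array_equal(new_keep, keep):
            keep = new_keep
            break
        keep = new_keep

    surviving = means[keep]
    med = float(np.median(surviving))
    mad = float(np.median(np.abs(surviving - med)))
    return BaselineEstimate(
        context=next(iter(contexts)),
        r2inf_s1=med,
        spread_s1=MAD_TO_SD * mad,
        n_supporting_residues=int(keep.sum()),
    )


def classify_regime(
    series: DispersionSeries,
    baseline: BaselineEstimate,
    z_threshold: float = 3.0,
) -> RegimeLabel:
    """Label one residue's profile as no_exchange / fast / dispersive.

    Amplitude A = r2eff(nu_min) - r2eff(nu_max) tested against its
    propagated error; mean elevation above the baseline tested against
    the larger of baseline spread and mean point error.
    """
    if series.context != baseline.context:
        raise ValueError("series and baseline contexts differ")
    r2 = np.asarray(series.r2eff_s1, dtype=float)
    sig = np.asarray(series.sigma_s1, dtype=float)

    amplitude = float(r2[0] - r2[-1])
    sigma_amp = float(math.hypot(sig[0], sig[-1]))
    elevation = float(np.mean(r2) - baseline.r2inf_s1)
    sigma_elev = float(max(baseline.spread_s1, np.mean(sig)))

    amp_z = amplitude / sigma_amp if sigma_amp > 0 else math.inf * np.sign(amplitude)
    elev_z = elevation / sigma_elev if sigma_elev > 0 else (
        math.inf if elevation > 0 else 0.0
    )

    if amplitude > z_threshold * sigma_amp:
        label = Regime.DISPERSIVE
    elif elevation > z_threshold * sigma_elev:
        label = Regime.FAST
    else:
        label = Regime.NO_EXCHANGE

    return RegimeLabel(
        residue_id=series.residue_id,
        context=series.context,
        label=label,
        mean_elevation_s1=elevation,
        amplitude_s1=amplitude,
        amplitude_z=float(amp_z),
        elevation_z=float(elev_z),
    )
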