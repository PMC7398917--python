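"""Reading, validation and writing of the delimited input/output tables.

Three table kinds are consumed by the pipeline:

* intensity tables   — residue, nu_cpmg, intensity, noise (+ optional
  context columns); the nu_cpmg = 0 row is the reference experiment,
* relaxation tables  — residue, R1, R1_err, R2, R2_err, NOE, NOE_err,
* shift tables       — residue, delta_H, delta_N.

All tables are plain CSV/TSV (delimiter auto-detected, ``#`` comments
allowed).  Grouping keys are ``(residue, context)`` and outputs are
deterministically sorted.
"""

from __future__ import annotations

import hashlib
import io
import logging
import re
from dataclasses import dataclass, field, replace
from pathlib import Path

import pandas as pd

from . import __version__

logger = logging.getLogger(__name__)

_RESIDUE_RE = re.compile(r"^\s*([A-Za-z]?)(\d+)([A-Za-z]?)\s*$")


class SchemaError(ValueError):
    """A required column is missing from an input table."""


class TableValidationError(ValueError):
    """Table contents violate an invariant (bad value, missing reference row...)."""


class TableParseError(ValueError):
    """A cell could not be parsed as a number."""


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class SpectrometerContext:
    """Acquisition context: field, temperature, CPMG constant time, sample."""

    proton_frequency_MHz: float
    temperature_K: float
    t_relax_s: float = 0.030
    field_T: float | None = None
    condition_label: str = "free"

    def __post_init__(self) -> None:
        if not self.proton_frequency_MHz > 0:
            raise ValueError("proton_frequency_MHz must be positive")
        if not self.t_relax_s > 0:
            raise ValueError("t_relax_s must be positive")
        if not 250.0 <= self.temperature_K <= 350.0:
            raise ValueError(
                f"temperature_K = {self.temperature_K} outside [250, 350]; "
                "temperatures are Kelvin, not Celsius"
            )

    @property
    def nitrogen_frequency_MHz(self) -> float:
        from .constants import NU_N_OVER_NU_H

        return self.proton_frequency_MHz * NU_N_OVER_NU_H


@dataclass(frozen=True)
class IntensityRecord:
    """One peak intensity at one CPMG frequency (0 = reference spectrum)."""

    residue_id: int
    nu_cpmg_s1: float
    intensity: float
    noise: float
    residue_code: str = ""

    def __post_init__(self) -> None:
        if not self.noise > 0:
            raise TableValidationError(
                f"residue {self.residue_id}: noise must be positive, got {self.noise}"
            )
        if self.nu_cpmg_s1 < 0:
            raise TableValidationError(
                f"residue {self.residue_id}: nu_cpmg must be >= 0"
            )

    @property
    def is_reference(self) -> bool:
        return self.nu_cpmg_s1 == 0.0


@dataclass(frozen=True)
class ShiftRecord:
    """Per-residue 1H/15N chemical shifts under one context."""

    residue_id: int
    delta_H_ppm: float
    delta_N_ppm: float
    context: SpectrometerContext
    residue_code: str = ""

    def __post_init__(self) -> None:
        import math

        if not (math.isfinite(self.delta_H_ppm) and math.isfinite(self.delta_N_ppm)):
            raise TableValidationError(
                f"residue {self.residue_id}: non-finite chemical shift"
            )


def parse_residue_id(value) -> tuple[int, str]:
    """Split a residue identifier into (number, one-letter code).

    Accepts ``86``, ``R86``, ``86R``; comparisons downstream use the
    integer only.
    """
    import numbers

    if isinstance(value, numbers.Integral) and not isinstance(value, bool):
        return int(value), ""
    if isinstance(value, numbers.Real) and float(value).is_integer():
        return int(value), ""
    s = str(value).strip()
    m = _RESIDUE_RE.match(s)
    if m is None:
        raise TableParseError(f"cannot parse residue identifier {value!r}")
    code = m.group(1) or m.group(3)
    return int(m.group(2)), code.upper()


# ---------------------------------------------------------------------------
# reading
# ---------------------------------------------------------------------------

def _detect_sep(path: Path) -> str:
    """Comma vs tab, decided from the first non-comment line."""
    with open(path) as fh:
        for line in fh:
            if line.strip() and not line.lstrip().startswith("#"):
                return "\t" if "\t" in line else ","
    return "\t"


def _read_table(path) -> pd.DataFrame:
    """Load a delimited table, auto-detecting comma vs tab."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, sep=_detect_sep(path), comment="#",
                     skip_blank_lines=True)
    df.columns = [str(c).strip() for c in df.columns]
    return df

def _require_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s): {', '.join(missing)}")

def _to_float(value, column: str, row: int) -> float:
    try:
        return float(value)
    except (TypeError, ValueError):
        raise TableParseError(
            f"row {row}: non-numeric value {value!r} in column {column!r}"
        ) from None


_CONTEXT_COLUMNS = {
    "proton_frequency_MHz": "proton_frequency_MHz",
    "field_MHz": "proton_frequency_MHz",
    "temperature_K": "temperature_K",
    "t_relax_s": "t_relax_s",
    "condition": "condition_label",
    "condition_label": "condition_label",
}


def _row_context(row, defaults: SpectrometerContext) -> SpectrometerContext:
    overrides = {}
    for col, attr in _CONTEXT_COLUMNS.items():
        if col in row.index and not pd.isna(row[col]):
            value = row[col]
            if attr != "condition_label":
                value = float(value)
            overrides[attr] = value
    return replace(defaults, **overrides) if overrides else defaults


def read_intensity_table(
    path, context_defaults: SpectrometerContext
) -> dict[tuple[int, SpectrometerContext], list[IntensityRecord]]:
    """Read a CPMG intensity table into groups keyed by (residue, context).

    Every group must contain exactly one reference row (nu_cpmg = 0).
    Groups are sorted by residue, rows by nu_cpmg.
    """
    df = _read_table(path)
    _require_columns(df, ["residue", "nu_cpmg", "intensity", "noise"], path)

    groups: dict[tuple[int, SpectrometerContext], list[IntensityRecord]] = {}
    for i, row in df.iterrows():
        resid, code = parse_residue_id(row["residue"])
        rec = IntensityRecord(
            residue_id=resid,
            residue_code=code,
            nu_cpmg_s1=_to_float(row["nu_cpmg"], "nu_cpmg", i),
            intensity=_to_float(row["intensity"], "intensity", i),
            noise=_to_float(row["noise"], "noise", i),
        )
        ctx = _row_context(row, context_defaults)
        groups.setdefault((resid, ctx), []).append(rec)

    for (resid, ctx), records in groups.items():
        n_ref = sum(r.is_reference for r in records)
        if n_ref == 0:
            raise TableValidationError(
                f"residue {resid}: no reference record (nu_cpmg = 0) "
                f"for condition {ctx.condition_label!r}"
            )
        if n_ref > 1:
            raise TableValidationError(
                f"residue {resid}: {n_ref} reference records; expected exactly one"
            )
        records.sort(key=lambda r: r.nu_cpmg_s1)

    return dict(sorted(groups.items(), key=lambda kv: (kv[0][0],
                                                       kv[0][1].condition_label,
                                                       kv[0][1].proton_frequency_MHz,
                                                       kv[0][1].temperature_K)))


def read_relaxation_table(path, context: SpectrometerContext):
    """Read an R1/R2/hetNOE table into RelaxationRecord objects."""
    from .relaxometry import RelaxationRecord  # deferred: avoids import cycle

    df = _read_table(path)
    _require_columns(
        df, ["residue", "R1", "R1_err", "R2", "R2_err", "NOE", "NOE_err"], path
    )
    records = []
    for i, row in df.iterrows():
        resid, code = parse_residue_id(row["residue"])
        records.append(
            RelaxationRecord(
                residue_id=resid,
                residue_code=code,
                context=context,
                R1_s1=_to_float(row["R1"], "R1", i),
                R1_err_s1=_to_float(row["R1_err"], "R1_err", i),
                R2_s1=_to_float(row["R2"], "R2", i),
                R2_err_s1=_to_float(row["R2_err"], "R2_err", i),
                hetNOE=_to_float(row["NOE"], "NOE", i),
                hetNOE_err=_to_float(row["NOE_err"], "NOE_err", i),
            )
        )
    records.sort(key=lambda r: r.residue_id)
    return records


def read_shift_table(path, context: SpectrometerContext) -> list[ShiftRecord]:
    """Read a chemical shift table; one record per residue."""
    df = _read_table(path)
    _require_columns(df, ["residue", "delta_H", "delta_N"], path)
    if df.empty:
        logger.warning("shift table %s is empty", path)
        return []
    records = []
    seen: set[int] = set()
    for i, row in df.iterrows():
        resid, code = parse_residue_id(row["residue"])
        if resid in seen:
            raise TableValidationError(
                f"duplicate residue {resid} for condition "
                f"{context.condition_label!r}"
            )
        seen.add(resid)
        records.append(
            ShiftRecord(
                residue_id=resid,
                residue_code=code,
                delta_H_ppm=_to_float(row["delta_H"], "delta_H", i),
                delta_N_ppm=_to_float(row["delta_N"], "delta_N", i),
                context=context,
            )
        )
    records.sort(key=lambda r: r.residue_id)
    return records


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------

def write_report(results: pd.DataFrame, path, fmt: str = "tsv",
                 units: dict[str, str] | None = None,
                 config: dict | None = None) -> Path:
    """Write a result table with a provenance header comment.

    The header records program version, a hash of the active config and
    per-column units.  Numbers are written at full (repr) precision so
    that a read-back round trip is lossless to < 1e-12 relative.
    """
    path = Path(path)
    sep = "\t" if fmt == "tsv" else ","
    cfg_repr = repr(sorted((config or {}).items())).encode()
    cfg_hash = hashlib.sha256(cfg_repr).hexdigest()[:12]

    buf = io.StringIO()
    buf.write(f"# relaxdisp {__version__}\n")
    buf.write(f"# config_hash: {cfg_hash}\n")
    if units:
        buf.write("# units: " + ", ".join(f"{k}={v}" for k, v in units.items()) + "\n")
    results.to_csv(buf, sep=sep, index=False, float_format="%.17g")
    try:
        path.write_text(buf.getvalue())
    except OSError as exc:
        raise OSError(f"cannot write report to {path}: {exc}") from exc
    return path


def read_report(path) -> pd.DataFrame:
    """Read back a table produced by :func:`write_report`."""
    path = Path(path)
    return pd.read_csv(path, sep=_detect_sep(path), comment="#")
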