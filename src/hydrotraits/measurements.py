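"""Core record types, unit conventions, CSV I/O and per-record calculators.

Sign convention used throughout the package: plant water potentials are
stored as signed megapascals (<= 0), while vulnerability-curve applied
pressures are positive MPa of tension.  The reader enforces the sign rule
on water-potential columns and auto-negates a column only when *every*
value in it is positive (a common data-entry convention), logging the
conversion.

Five CSV schemas are understood (see ``SCHEMAS``):

``water_potential``  plant_id, day, psi_pd, psi_min [, cultivar, treatment]
``gas_exchange``     plant_id, day, a_n, gs, e, ci [, cultivar, treatment]
``pot_weights``      plant_id, day, pot, pot_dry, pot_wet [, cultivar, treatment]
``vulnerability``    stem_id, pressure_mpa, kh [, kmax, cultivar]
``pv_curve``         leaf_id, psi_mpa, fresh_mass_g, dry_mass_g, sat_mass_g,
                     leaf_area_m2 [, cultivar]
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

from .errors import InvalidRecordError, SchemaError, logger

MOLAR_MASS_WATER = 18.015  # g mol^-1


# ---------------------------------------------------------------------------
# Record types
# ---------------------------------------------------------------------------

@dataclass
class WaterPotentialRecord:
    """Paired pre-dawn / midday leaf water potential for one plant on one day.

    ``psi_pd`` and ``psi_min`` are signed MPa (<= 0).  A record with
    ``psi_min > psi_pd`` is physically inconsistent (leaves cannot be wetter
    at midday than at pre-dawn under steady drying); it is flagged, never
    silently dropped.
    """

    plant_id: str
    day: int
    psi_pd: float
    psi_min: float
    cultivar: str = ""
    treatment: str = "PD"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.psi_min > self.psi_pd:
            self.flags = self.flags + ("psi_min_above_psi_pd",)


@dataclass
class GasExchangeRecord:
    """Midday gas-exchange observation.

    Units: ``a_n`` µmol CO2 m-2 s-1, ``gs`` and ``e`` mmol H2O m-2 s-1,
    ``ci`` ppm.  ``iwue`` (mmol CO2 mol-1 H2O) is derived per record as
    A_N / E; averaging across records happens downstream so treatment means
    are means of individual ratios, never a ratio of means.
    """

    plant_id: str
    day: int
    a_n: float
    gs: float
    e: float
    ci: float = float("nan")
    cultivar: str = ""
    treatment: str = "PD"
    flags: tuple[str, ...] = ()

    @property
    def iwue(self) -> float:
        if self.e <= 0:
            return float("nan")
        return compute_iwue(self.a_n, self.e)

    def __post_init__(self) -> None:
        if self.e <= 0:
            self.flags = self.flags + ("nonpositive_transpiration",)
        if self.gs < 0:
            self.flags = self.flags + ("negative_gs",)


@dataclass
class PotWeightRecord:
    """Pot + substrate weight (kg) with its oven-dry and container-capacity
    references, from which gravimetric substrate water content is derived."""

    plant_id: str
    day: int
    pot: float
    pot_dry: float
    pot_wet: float
    cultivar: str = ""
    treatment: str = "PD"
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.pot_dry >= self.pot_wet:
            raise InvalidRecordError(
                f"pot_dry ({self.pot_dry}) must be < pot_wet ({self.pot_wet}) "
                f"for plant {self.plant_id} day {self.day}"
            )
        if self.pot < self.pot_dry:
            self.flags = self.flags + ("pot_below_dry_weight",)


# ---------------------------------------------------------------------------
# Closed-form per-record calculators
# ---------------------------------------------------------------------------

def compute_gwc(rec: PotWeightRecord) -> float:
    """Gravimetric substrate water content (%) of one pot weighing.

    GWC = 100 * (pot - pot_dry) / (pot_wet - pot_dry).  Exactly 0 at the
    oven-dry weight and 100 at container capacity; values slightly above
    100 (pot heavier than at capacity) are kept and flagged, not clipped.
    """
    denom = rec.pot_wet - rec.pot_dry
    if denom <= 0:
        raise InvalidRecordError(
            f"zero or negative capacity denominator for plant {rec.plant_id}"
        )
    gwc = 100.0 * (rec.pot - rec.pot_dry) / denom
    if gwc > 100.0:
        rec.flags = rec.flags + ("gwc_above_capacity",)
    return gwc


def compute_plc(kh: float, kmax: float) -> float:
    """Percentage loss of hydraulic conductivity relative to the flushed maximum.

    PLC = 100 * (1 - kh / kmax), clipped to [0, 100].  ``kh`` marginally
    above ``kmax`` happens routinely with gravimetric flow measurements; the
    clip is logged as a warning rather than raised.
    """
    if kmax <= 0:
        raise InvalidRecordError(f"kmax must be positive, got {kmax}")
    if kh < 0:
        raise InvalidRecordError(f"kh must be non-negative, got {kh}")
    plc = 100.0 * (1.0 - kh / kmax)
    if plc < 0.0 or plc > 100.0:
        logger.warning("PLC %.3f outside [0, 100] (kh=%g, kmax=%g); clipped", plc, kh, kmax)
        plc = min(max(plc, 0.0), 100.0)
    return plc


def compute_iwue(a_n: float, e: float) -> float:
    """Instantaneous water-use efficiency A_N / E (mmol CO2 mol-1 H2O)."""
    if e <= 0:
        raise InvalidRecordError(f"transpiration must be positive, got {e}")
    return a_n / e


def compute_rwc(fresh_mass, dry_mass: float, sat_mass: float):
    """Relative water content (%) of leaf fresh-mass readings.

    RWC = 100 * (fresh - dry) / (sat - dry).  Accepts a scalar or array of
    fresh masses.
    """
    if sat_mass <= dry_mass:
        raise InvalidRecordError(
            f"saturated mass ({sat_mass}) must exceed dry mass ({dry_mass})"
        )
    fresh = np.asarray(fresh_mass, dtype=float)
    if np.any(fresh < dry_mass):
        raise InvalidRecordError("fresh mass below dry mass in series")
    out = 100.0 * (fresh - dry_mass) / (sat_mass - dry_mass)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# CSV I/O
# ---------------------------------------------------------------------------

#: schema name -> (required columns, optional columns, water-potential columns)
SCHEMAS: dict[str, tuple[tuple[str, ...], tuple[str, ...], tuple[str, ...]]] = {
    "water_potential": (
        ("plant_id", "day", "psi_pd", "psi_min"),
        ("cultivar", "treatment"),
        ("psi_pd", "psi_min"),
    ),
    "gas_exchange": (
        ("plant_id", "day", "a_n", "gs", "e"),
        ("ci", "cultivar", "treatment"),
        (),
    ),
    "pot_weights": (
        ("plant_id", "day", "pot", "pot_dry", "pot_wet"),
        ("cultivar", "treatment"),
        (),
    ),
    "vulnerability": (
        ("stem_id", "pressure_mpa", "kh"),
        ("kmax", "cultivar"),
        (),
    ),
    "pv_curve": (
        ("leaf_id", "psi_mpa", "fresh_mass_g", "dry_mass_g", "sat_mass_g"),
        ("leaf_area_m2", "cultivar"),
        ("psi_mpa",),
    ),
}

_RECORD_CLASSES = {
    "water_potential": WaterPotentialRecord,
    "gas_exchange": GasExchangeRecord,
    "pot_weights": PotWeightRecord,
}


def _validate_frame(df: pd.DataFrame, schema: str) -> pd.DataFrame:
    required, optional, psi_cols = SCHEMAS[schema]
    unknown = [c for c in df.columns if c not in required + optional]
    if unknown:
        raise SchemaError(f"{schema}: unknown columns {unknown}")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{schema}: missing required columns {missing}")

    numeric = [c for c in df.columns if c not in ("plant_id", "stem_id", "leaf_id",
                                                  "cultivar", "treatment")]
    for col in numeric:
        coerced = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[coerced.isna() & df[col].notna()].tolist()
        if bad:
            raise SchemaError(f"{schema}: non-numeric values in '{col}' at rows {bad}")
        df[col] = coerced

    # sign rule for water-potential columns: all <= 0 is canonical; all > 0
    # triggers a logged auto-negate; a mixture is a schema error.
    for col in psi_cols:
        vals = df[col].dropna()
        if len(vals) == 0:
            continue
        if (vals > 0).all():
            logger.warning("%s: column '%s' all-positive; auto-negating (sign rule)",
                           schema, col)
            df[col] = -df[col]
        elif (vals > 0).any():
            rows = df.index[df[col] > 0].tolist()
            raise SchemaError(
                f"{schema}: mixed signs in water-potential column '{col}' at rows {rows}"
            )
    return df


def read_table(path: str | Path, schema: str) -> list:
    """Read and validate one of the five documented CSV schemas.

    Returns a list of typed records for the three record-shaped schemas, or
    the validated :class:`pandas.DataFrame` for ``vulnerability`` and
    ``pv_curve`` (those are consumed curve-wise by their fitting modules).
    An empty file yields an empty collection with a logged warning.
    """
    if schema not in SCHEMAS:
        raise SchemaError(f"unknown schema '{schema}'; expected one of {sorted(SCHEMAS)}")
    path = Path(path)
    try:
        df = pd.read_csv(path, float_precision="round_trip")
    except pd.errors.EmptyDataError:
        logger.warning("%s: empty file %s", schema, path)
        return []
    if df.empty:
        logger.warning("%s: no data rows in %s", schema, path)
        return []
    df = _validate_frame(df, schema)
    if schema not in _RECORD_CLASSES:
        return df

    cls = _RECORD_CLASSES[schema]
    valid = {f.name for f in fields(cls)}
    records = []
    for row in df.to_dict("records"):
        kwargs = {k: v for k, v in row.items() if k in valid and pd.notna(v)}
        kwargs["day"] = int(kwargs["day"])
        records.append(cls(**kwargs))
    return records


def write_table(records: Iterable, path: str | Path, schema: str | None = None) -> pd.DataFrame:
    """Write records (or a DataFrame) back to CSV; inverse of :func:`read_table`.

    Floats are written with Python's shortest round-tripping repr, so
    ``read_table(write_table(X))`` reproduces finite values bit-exactly.
    """
    if isinstance(records, pd.DataFrame):
        df = records
    else:
        rows = []
        for r in records:
            d = {f.name: getattr(r, f.name) for f in fields(r) if f.name != "flags"}
            rows.append(d)
        df = pd.DataFrame(rows)
    df.to_csv(path, index=False, float_format="%.17g")
    return df
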