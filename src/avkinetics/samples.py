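"""Sample-table schema, readers/writers and unit normalisation.

The exchange dialect is a delimited text table (CSV or TSV) in long format,
one row per measurement:

======================  =======================================================
column                  meaning
======================  =======================================================
``animal_id``           experimental unit identifier
``group``               diet group, ``control`` or ``treatment``
``site``                sampling site, ``artery`` or ``vein``
``time_h``              hours from the first feeding (>= 0; baseline = 0)
``analyte``             ``leucine``, ``kic``, ``co2`` or ``pah``
``concentration``       plasma concentration in ``conc_unit``
``conc_unit``           ``umol/L`` (leucine, KIC), ``mmol/L`` accepted for CO2,
                        ``mg/L`` for the PAH indicator
``enrichment_mpe``      isotopic enrichment as mole percent excess (absent for
                        PAH; may be left blank when ``ion_ratio`` is supplied)
``ion_ratio``           raw M+1/M ion-intensity ratio, optional
``body_weight_kg``      optional, constant per animal
======================  =======================================================

Enum-valued columns are canonicalised case-insensitively (``Artery`` ->
``artery``); unknown values are rejected with the offending line number.
Unknown extra columns are preserved untouched.

Internally the pipeline works on a normalised copy of the table in which all
concentrations are in canonical units (umol/L; mg/L for PAH) and enrichment is
a fraction in ``enrichment_frac`` (MPE / 100).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd

from .errors import SchemaError, UnitError

GROUPS = ("control", "treatment")
SITES = ("artery", "vein")
ANALYTES = ("leucine", "kic", "co2", "pah")

_SITE_ALIASES = {
    "artery": "artery", "art": "artery", "a": "artery",
    "arterial": "artery", "carotid": "artery",
    "vein": "vein", "ven": "vein", "v": "vein",
    "venous": "vein", "femoral": "vein",
}
_ANALYTE_ALIASES = {
    "leucine": "leucine", "leu": "leucine",
    "kic": "kic", "a-kic": "kic", "alpha-kic": "kic", "ketoisocaproate": "kic",
    "co2": "co2", "13co2": "co2", "bicarbonate": "co2",
    "pah": "pah", "p-aminohippurate": "pah",
}
_GROUP_ALIASES = {"control": "control", "ctrl": "control",
                  "treatment": "treatment", "treat": "treatment", "bcaa": "treatment"}

#: canonical concentration unit per analyte
CANONICAL_UNITS = {"leucine": "umol/L", "kic": "umol/L", "co2": "umol/L", "pah": "mg/L"}

#: factor converting a recognised unit to the analyte's canonical unit
_UNIT_FACTORS = {
    ("umol/L", "umol/L"): 1.0,
    ("mmol/L", "umol/L"): 1000.0,
    ("mg/L", "mg/L"): 1.0,
}
_UNIT_ALIASES = {
    "umol/l": "umol/L", "µmol/l": "umol/L", "μmol/l": "umol/L", "umol_l": "umol/L",
    "mmol/l": "mmol/L", "mg/l": "mg/L",
}

REQUIRED_COLUMNS = ("animal_id", "group", "site", "time_h",
                    "analyte", "concentration", "conc_unit")
OPTIONAL_COLUMNS = ("enrichment_mpe", "ion_ratio", "body_weight_kg")


@dataclass(frozen=True)
class SampleRecord:
    """One measurement row, validated.

    Mostly useful for constructing small fixtures by hand; bulk data flows
    through :class:`pandas.DataFrame` tables with the same fields as columns.
    """

    animal_id: str
    group: str
    site: str
    time_h: float
    analyte: str
    concentration: float
    conc_unit: str = "umol/L"
    enrichment_mpe: Optional[float] = None
    ion_ratio: Optional[float] = None
    body_weight_kg: Optional[float] = None

    def __post_init__(self):
        object.__setattr__(self, "group", canonical_enum(self.group, _GROUP_ALIASES, "group"))
        object.__setattr__(self, "site", canonical_enum(self.site, _SITE_ALIASES, "site"))
        object.__setattr__(self, "analyte", canonical_enum(self.analyte, _ANALYTE_ALIASES, "analyte"))
        object.__setattr__(self, "conc_unit", canonical_unit(self.conc_unit))
        if self.time_h < 0:
            raise SchemaError(f"time_h must be >= 0, got {self.time_h}")
        if self.concentration < 0:
            raise SchemaError(f"concentration must be >= 0, got {self.concentration}")
        if self.enrichment_mpe is not None and not (0 <= self.enrichment_mpe < 100):
            raise SchemaError(f"enrichment_mpe must lie in [0, 100), got {self.enrichment_mpe}")


def canonical_enum(value, aliases, field):
    key = str(value).strip().lower()
    if key not in aliases:
        raise SchemaError(f"unknown {field} value {value!r}")
    return aliases[key]


def canonical_unit(unit):
    key = str(unit).strip().lower()
    if key not in _UNIT_ALIASES:
        raise UnitError(f"unknown concentration unit {unit!r}")
    return _UNIT_ALIASES[key]


def records_to_frame(records) -> pd.DataFrame:
    """Assemble :class:`SampleRecord` objects into the long-format table."""
    return pd.DataFrame([vars(r) for r in records])


def validate_samples(df: pd.DataFrame) -> pd.DataFrame:
    """Validate and canonicalise a raw sample table.

    Returns a copy with enum columns canonicalised and numeric columns
    coerced.  Raises :class:`SchemaError` naming the column (and data line,
    counting the header as line 1) on the first violation.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"sample table missing required column(s): {', '.join(missing)}")
    out = df.copy()
    for col, aliases in (("group", _GROUP_ALIASES), ("site", _SITE_ALIASES),
                         ("analyte", _ANALYTE_ALIASES)):
        canon = out[col].astype(str).str.strip().str.lower().map(aliases)
        bad = out.index[canon.isna()]
        if len(bad):
            i = bad[0]
            raise SchemaError(
                f"unknown {col} value {out.loc[i, col]!r} (data line {int(i) + 2})")
        out[col] = canon
    out["conc_unit"] = [canonical_unit(u) for u in out["conc_unit"]]
    for col in ("time_h", "concentration", "enrichment_mpe", "ion_ratio", "body_weight_kg"):
        if col in out.columns:
            try:
                out[col] = pd.to_numeric(out[col])
            except (ValueError, TypeError) as exc:
                raise SchemaError(f"non-numeric value in column {col!r}: {exc}") from None
    if (out["time_h"] < 0).any():
        i = out.index[out["time_h"] < 0][0]
        raise SchemaError(f"negative time_h (data line {int(i) + 2})")
    if (out["concentration"] < 0).any():
        i = out.index[out["concentration"] < 0][0]
        raise SchemaError(f"negative concentration (data line {int(i) + 2})")
    if "enrichment_mpe" in out.columns:
        e = out["enrichment_mpe"].dropna()
        if ((e < 0) | (e >= 100)).any():
            raise SchemaError("enrichment_mpe outside [0, 100)")
    out["animal_id"] = out["animal_id"].astype(str)
    return out


def read_samples(path, sep=None) -> pd.DataFrame:
    """Read and validate a sample table from a CSV/TSV file.

    ``sep=None`` sniffs comma versus tab from the header line.
    """
    df = pd.read_csv(path, sep=sep, engine="python" if sep is None else "c")
    df.columns = [str(c).strip() for c in df.columns]
    return validate_samples(df)


def write_samples(df: pd.DataFrame, path) -> None:
    """Write a sample table in the external dialect (RFC-4180 CSV)."""
    out = df.copy()
    if "enrichment_frac" in out.columns and "enrichment_mpe" not in out.columns:
        out["enrichment_mpe"] = out.pop("enrichment_frac") * 100.0
    out.to_csv(path, index=False)


def normalize_units(df: pd.DataFrame) -> pd.DataFrame:
    """Convert a validated table to canonical internal units.

    Concentrations become umol/L (mg/L for the PAH indicator); enrichment is
    re-expressed as the fraction column ``enrichment_frac`` and the external
    ``enrichment_mpe`` column is dropped.  Idempotent: applying twice equals
    applying once.
    """
    out = df.copy()
    if "enrichment_mpe" in out.columns:
        out["enrichment_frac"] = out["enrichment_mpe"] / 100.0
        out = out.drop(columns=["enrichment_mpe"])
    elif "enrichment_frac" not in out.columns:
        out["enrichment_frac"] = np.nan
    factors = np.ones(len(out))
    for i, (analyte, unit) in enumerate(zip(out["analyte"], out["conc_unit"])):
        target = CANONICAL_UNITS[analyte]
        try:
            factors[i] = _UNIT_FACTORS[(unit, target)]
        except KeyError:
            raise UnitError(
                f"cannot convert {analyte} concentration from {unit!r} to {target!r}"
            ) from None
    out["concentration"] = out["concentration"] * factors
    out["conc_unit"] = out["analyte"].map(CANONICAL_UNITS)
    return out


def body_weights(df: pd.DataFrame, default: float = 20.0) -> dict:
    """Per-animal body weight (kg) from the optional ``body_weight_kg`` column.

    Animals without a recorded weight fall back to ``default`` (the cohort in
    this protocol weighs ~20 kg at study) with a logged warning.
    """
    weights = {}
    have = df["body_weight_kg"].notna() if "body_weight_kg" in df.columns else None
    for animal, sub in df.groupby("animal_id"):
        w = sub["body_weight_kg"].dropna().unique() if have is not None else []
        if len(w) > 1:
            raise SchemaError(f"animal {animal!r} has conflicting body weights {w}")
        if len(w) == 1:
            weights[animal] = float(w[0])
        else:
            warnings.warn(
                f"no body weight recorded for animal {animal!r}; using {default} kg")
            weights[animal] = default
    return weights
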