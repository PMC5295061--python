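"""Isotopic enrichment from raw ion-intensity ratios.

Single-label GC/LC-MS work measures the intensity ratio of the M+1 to the M
isotopomer (m/z 302/303 for AQC-derivatised leucine in positive mode, 129/130
for underivatised KIC in negative mode).  Subtracting the natural-abundance
background ratio of a pre-infusion sample gives the tracer-to-tracee ratio
(TTR), and mole percent excess follows as

    MPE = 100 * TTR / (1 + TTR).

No multi-isotopomer matrix correction is attempted: with a single label the
background subtraction is the whole correction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import InvalidMeasurementError


@dataclass(frozen=True)
class TracerToTraceeRatio:
    """A background-corrected tracer-to-tracee ratio.

    ``clamped`` records that the raw excess was negative (measurement noise
    around natural abundance) and was clamped to zero under the default
    policy.
    """

    ttr: float
    clamped: bool = False


def compute_ttr(ratio_sample: float, ratio_background: float,
                policy: str = "clamp") -> TracerToTraceeRatio:
    """Background-correct an ion ratio into a TTR.

    Parameters
    ----------
    ratio_sample, ratio_background
        M+1/M intensity ratios of the enriched sample and of the baseline
        (pre-infusion) sample from the same animal, site and analyte.
    policy
        ``"clamp"`` (default) clamps small negative excesses to zero and
        flags them; ``"raise"`` raises instead.
    """
    if ratio_sample < 0 or ratio_background < 0:
        raise InvalidMeasurementError(
            f"ion ratios must be >= 0, got sample={ratio_sample}, "
            f"background={ratio_background}")
    ttr = ratio_sample - ratio_background
    if ttr < 0:
        if policy == "raise":
            raise InvalidMeasurementError(
                f"corrected TTR is negative ({ttr:.4g})")
        if policy != "clamp":
            raise ValueError(f"unknown negative-TTR policy {policy!r}")
        warnings.warn(f"negative corrected TTR ({ttr:.4g}) clamped to 0")
        return TracerToTraceeRatio(0.0, clamped=True)
    return TracerToTraceeRatio(float(ttr))


def mpe_from_ttr(ttr):
    """Mole percent excess (%) from a TTR; strictly below 100 and monotone."""
    t = ttr.ttr if isinstance(ttr, TracerToTraceeRatio) else ttr
    t = np.asarray(t, dtype=float)
    if np.any(t < 0):
        raise InvalidMeasurementError("TTR must be >= 0")
    out = 100.0 * t / (1.0 + t)
    return float(out) if out.ndim == 0 else out


def ttr_from_mpe(mpe):
    """Inverse of :func:`mpe_from_ttr` on [0, 100)."""
    m = np.asarray(mpe, dtype=float)
    if np.any((m < 0) | (m >= 100)):
        raise InvalidMeasurementError("MPE must lie in [0, 100)")
    out = m / (100.0 - m)
    return float(out) if out.ndim == 0 else out


def enrichment_from_ion_ratios(df: pd.DataFrame, baseline_time: float = 0.0,
                               policy: str = "clamp") -> pd.DataFrame:
    """Fill missing ``enrichment_mpe`` from raw ``ion_ratio`` columns.

    For every (animal, site, analyte) series the ratio measured at
    ``baseline_time`` serves as the natural-abundance background; rows whose
    enrichment is already present are left untouched.
    """
    if "ion_ratio" not in df.columns:
        return df
    out = df.copy()
    if "enrichment_mpe" not in out.columns:
        out["enrichment_mpe"] = np.nan
    for (animal, site, analyte), idx in out.groupby(
            ["animal_id", "site", "analyte"]).groups.items():
        sub = out.loc[idx]
        need = sub["enrichment_mpe"].isna() & sub["ion_ratio"].notna()
        if not need.any():
            continue
        base = sub.loc[sub["time_h"] == baseline_time, "ion_ratio"].dropna()
        if base.empty:
            raise InvalidMeasurementError(
                f"no baseline ion ratio at t={baseline_time} h for "
                f"{analyte}@{site} of animal {animal!r}")
        bg = float(base.iloc[0])
        for i in sub.index[need]:
            ttr = compute_ttr(float(sub.loc[i, "ion_ratio"]), bg, policy=policy)
            out.loc[i, "enrichment_mpe"] = mpe_from_ttr(ttr)
    return out
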