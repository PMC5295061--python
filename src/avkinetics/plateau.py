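"""Isotopic/concentration steady-state (plateau) identification.

A primed-continuous infusion approaches its plateau exponentially; all
downstream kinetics use only the plateau values.  Three rules are provided:

``last_k_plateau``
    The study rule: the arithmetic mean of the final *k* samples (k = 3 for
    the leucine/KIC phase).
``fixed_timepoint_summary``
    A single named sample, used for the bicarbonate phase (the 2-h sample).
``detect_plateau``
    A stricter optional detector: the longest trailing window whose
    least-squares slope is not significantly different from zero and whose
    CV stays below a threshold, falling back to ``last_k_plateau`` with a
    warning when no window qualifies.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

from .errors import InsufficientDataError, MissingSampleError


@dataclass(frozen=True)
class PlateauWindow:
    """Plateau summary of a single time series."""

    mean: float
    cv_percent: float
    window: tuple          # the time points included, hours
    n_points: int
    fallback: bool = False  # detector fell back to the last-k rule


@dataclass(frozen=True)
class SteadyStateSummary:
    """Plateau concentration and enrichment for one analyte at one site."""

    analyte: str
    site: str
    window: tuple
    mean_concentration: float            # canonical units (umol/L; mg/L PAH)
    mean_enrichment: Optional[float]     # fraction, None for PAH
    cv_concentration_percent: float
    cv_enrichment_percent: Optional[float]
    n_points: int
    flags: tuple = field(default=())


def _clean(times, values):
    t = np.asarray(times, dtype=float)
    v = np.asarray(values, dtype=float)
    if t.shape != v.shape or t.ndim != 1:
        raise ValueError("times and values must be 1-D arrays of equal length")
    keep = ~np.isnan(v)
    dropped = int((~keep).sum())
    if dropped:
        warnings.warn(f"{dropped} missing sample(s) dropped from plateau series")
    t, v = t[keep], v[keep]
    order = np.argsort(t, kind="stable")
    return t[order], v[order]


def _cv_percent(v):
    m = float(np.mean(v))
    if len(v) < 2:
        return 0.0
    s = float(np.std(v, ddof=1))
    if s == 0.0:
        return 0.0
    if m == 0.0:
        return float("inf")
    return 100.0 * s / abs(m)


def last_k_plateau(times, values, k: int = 3) -> PlateauWindow:
    """Mean and CV over the final ``k`` samples of a time-ordered series."""
    if k < 2:
        raise ValueError("k must be >= 2")
    t, v = _clean(times, values)
    if len(v) < k:
        raise InsufficientDataError(
            f"need at least {k} samples for a last-{k} plateau, got {len(v)}")
    tw, vw = t[-k:], v[-k:]
    return PlateauWindow(mean=float(np.mean(vw)), cv_percent=_cv_percent(vw),
                         window=tuple(tw), n_points=k)


def fixed_timepoint_summary(times, values, time_h: float) -> PlateauWindow:
    """Single-sample summary at an exact time point (bicarbonate-phase rule)."""
    t, v = _clean(times, values)
    hit = np.isclose(t, time_h)
    if not hit.any():
        raise MissingSampleError(f"no sample at t = {time_h} h")
    val = float(v[hit][0])
    return PlateauWindow(mean=val, cv_percent=0.0, window=(float(time_h),),
                         n_points=1)


def detect_plateau(times, values, alpha: float = 0.05, min_window: int = 3,
                   cv_threshold: float = 15.0) -> PlateauWindow:
    """Longest trailing window with a statistically flat slope and bounded CV.

    Scans trailing windows from the full series down to ``min_window``; the
    first (longest) window whose regression slope is not significantly
    different from zero at ``alpha`` and whose CV <= ``cv_threshold`` %
    wins.  Falls back to :func:`last_k_plateau` with a warning when no
    window qualifies.
    """
    t, v = _clean(times, values)
    n = len(v)
    if n < min_window:
        raise InsufficientDataError(
            f"need at least {min_window} samples, got {n}")
    for w in range(n, min_window - 1, -1):
        tw, vw = t[-w:], v[-w:]
        if np.ptp(vw) == 0.0:
            p_slope = 1.0  # exactly constant: slope is exactly zero
        else:
            res = stats.linregress(tw, vw)
            p_slope = res.pvalue if np.isfinite(res.pvalue) else 1.0
        if p_slope > alpha and _cv_percent(vw) <= cv_threshold:
            return PlateauWindow(mean=float(np.mean(vw)),
                                 cv_percent=_cv_percent(vw),
                                 window=tuple(tw), n_points=w)
    warnings.warn("no flat trailing window found; falling back to the "
                  f"last-{min_window} rule")
    base = last_k_plateau(t, v, k=min_window)
    return PlateauWindow(mean=base.mean, cv_percent=base.cv_percent,
                         window=base.window, n_points=base.n_points,
                         fallback=True)


# ---------------------------------------------------------------------------
# table-level driver

def animal_steady_states(df, rule: str = "last3", k: int = 3,
                         co2_time_h: float = 2.0, alpha: float = 0.05,
                         cv_threshold: float = 15.0) -> dict:
    """Steady-state summaries for one animal's normalised sample table.

    Returns ``{(analyte, site): SteadyStateSummary}``.  Leucine, KIC and the
    PAH indicator use the configured plateau rule (default: mean of the last
    three samples); CO2 uses the single bicarbonate-phase sample at
    ``co2_time_h``.

    Parameters
    ----------
    df
        Normalised long-format table (see :func:`avkinetics.samples.normalize_units`)
        restricted to a single animal.
    rule
        ``"last3"`` (study rule) or ``"detect"`` (slope-test detector).
    """
    if rule not in ("last3", "detect"):
        raise ValueError(f"unknown plateau rule {rule!r}")
    summaries = {}
    for (analyte, site), sub in df.groupby(["analyte", "site"]):
        sub = sub.sort_values("time_h")
        t = sub["time_h"].to_numpy(float)
        conc = sub["concentration"].to_numpy(float)
        enr = sub["enrichment_frac"].to_numpy(float) if "enrichment_frac" in sub else np.full(len(sub), np.nan)
        flags = []
        if analyte == "co2":
            cw = fixed_timepoint_summary(t, conc, co2_time_h)
            ew = fixed_timepoint_summary(t, enr, co2_time_h)
        elif rule == "detect" and analyte != "pah":
            cw = detect_plateau(t, conc, alpha=alpha, min_window=k,
                                cv_threshold=cv_threshold)
            ew = (detect_plateau(t, enr, alpha=alpha, min_window=k,
                                 cv_threshold=cv_threshold)
                  if np.isfinite(enr).any() else None)
            if cw.fallback or (ew is not None and ew.fallback):
                flags.append("plateau-fallback")
        else:
            cw = last_k_plateau(t, conc, k=k)
            ew = last_k_plateau(t, enr, k=k) if np.isfinite(enr).any() else None
        has_enr = analyte != "pah" and ew is not None and np.isfinite(ew.mean)
        summaries[(analyte, site)] = SteadyStateSummary(
            analyte=analyte, site=site, window=cw.window,
            mean_concentration=cw.mean,
            mean_enrichment=(ew.mean if has_enr else None),
            cv_concentration_percent=cw.cv_percent,
            cv_enrichment_percent=(ew.cv_percent if has_enr else None),
            n_points=cw.n_points, flags=tuple(flags))
    return summaries


def steady_state_frame(summaries_by_animal: dict):
    """Flatten ``{animal: {(analyte, site): SteadyStateSummary}}`` to a table."""
    import pandas as pd

    rows = []
    for animal, summaries in summaries_by_animal.items():
        for (analyte, site), s in summaries.items():
            rows.append({
                "animal_id": animal, "analyte": analyte, "site": site,
                "window_start_h": s.window[0], "window_end_h": s.window[-1],
                "n_points": s.n_points,
                "mean_concentration": s.mean_concentration,
                "mean_enrichment": s.mean_enrichment,
                "cv_concentration_percent": s.cv_concentration_percent,
                "cv_enrichment_percent": s.cv_enrichment_percent,
                "flags": ";".join(s.flags),
            })
    return pd.DataFrame(rows)
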