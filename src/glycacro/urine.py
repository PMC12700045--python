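"""Timed urinary excretion of the acrolein mercapturic acids.

Acrolein is detoxified by glutathione conjugation and excreted in urine as
two mercapturic acids: 3-HPMA (N-acetyl-S-(3-hydroxypropyl)-L-cysteine,
C8H15NO4S) and its oxidized counterpart CEMA
(N-acetyl-S-(carboxyethyl)-L-cysteine, C8H13NO5S).  Urine is collected in
timed intervals of 1-24 h; each interval carries a weight (volume follows
from an assumed density of 1 kg/L) and analyte concentrations in ng/mL.

This module converts concentrations to excreted amounts (umol) and
aggregates them into study days (08:00 to 08:00) and overnight windows
(20:00 to 08:00).  An interval that straddles a window boundary is
pro-rated by the fraction of its duration inside the window, which assumes
uniform excretion within the interval and conserves total amount under any
partition of the timeline.
"""

from __future__ import annotations

from dataclasses import dataclass
from datetime import time

import numpy as np
import pandas as pd

__all__ = [
    "MW_HPMA",
    "MW_CEMA",
    "AnalyteConstants",
    "WindowSpec",
    "interval_volume",
    "interval_amount",
    "add_interval_amounts",
    "daily_excretion",
    "overnight_excretion",
    "daily_ratio",
    "UrineValidationError",
]

# Molar masses from the molecular formulas (IUPAC 2021 atomic weights):
# 3-HPMA C8H15NO4S, CEMA C8H13NO5S.
MW_HPMA = 221.27
MW_CEMA = 235.25


class UrineValidationError(ValueError):
    """Raised when a urine interval table violates its invariants."""


@dataclass(frozen=True)
class AnalyteConstants:
    """Physico-chemical constants of the ng/mL -> umol conversion."""

    mw_hpma: float = MW_HPMA  # g/mol
    mw_cema: float = MW_CEMA  # g/mol
    urine_density: float = 1.0  # kg/L

    def __post_init__(self) -> None:
        if self.mw_hpma <= 0 or self.mw_cema <= 0:
            raise UrineValidationError("molar masses must be positive")
        if self.urine_density <= 0:
            raise UrineValidationError("urine density must be positive")


@dataclass(frozen=True)
class WindowSpec:
    """Clock-time windows of the collection scheme.

    The study day runs 08:00 to 08:00 the next morning (the intervention
    started at 8 a.m.); the overnight window attributed to a dinner runs
    20:00 to 08:00.  Windows are half-open ``[start, end)``.
    """

    overnight_start: time = time(20, 0)
    overnight_end: time = time(8, 0)
    day_boundary: time = time(8, 0)
    prorate: bool = True  # False: assign whole interval to the window of its midpoint


DEFAULT_WINDOWS = WindowSpec()


def interval_volume(urine_weight_g: float, density_kg_l: float = 1.0) -> float:
    """Urine volume in litres from its weight in grams."""
    if urine_weight_g < 0:
        raise UrineValidationError(f"negative urine weight {urine_weight_g} g")
    if density_kg_l <= 0:
        raise UrineValidationError(f"non-positive density {density_kg_l} kg/L")
    return (urine_weight_g / 1000.0) / density_kg_l


def interval_amount(conc_ng_ml: float, volume_l: float, mw_g_mol: float) -> float:
    """Excreted amount in umol from a concentration and a volume.

    ng/mL x mL gives ng; dividing by the molar mass gives nmol; /1000
    gives umol.
    """
    if mw_g_mol <= 0:
        raise UrineValidationError(f"non-positive molar mass {mw_g_mol}")
    if conc_ng_ml < 0 or volume_l < 0:
        raise UrineValidationError("concentration and volume must be >= 0")
    return conc_ng_ml * (volume_l * 1000.0) / mw_g_mol / 1000.0


def _hours_since(ts: pd.Series, origin: pd.Timestamp) -> np.ndarray:
    return (pd.to_datetime(ts) - origin).dt.total_seconds().to_numpy() / 3600.0


def _study_origin(intervals: pd.DataFrame, windows: WindowSpec) -> pd.Timestamp:
    """08:00 on the first collection date: hour zero of study day 1."""
    first = pd.to_datetime(intervals["start"]).min()
    origin = first.normalize() + pd.Timedelta(
        hours=windows.day_boundary.hour, minutes=windows.day_boundary.minute
    )
    if first < origin:  # first interval starts before 08:00 of its date
        origin -= pd.Timedelta(days=1)
    return origin


def _validate_no_overlap(intervals: pd.DataFrame) -> None:
    offenders = []
    for pid, chunk in intervals.groupby("participant"):
        chunk = chunk.sort_values("start")
        starts = pd.to_datetime(chunk["start"]).to_numpy()
        ends = pd.to_datetime(chunk["end"]).to_numpy()
        if (ends <= starts).any():
            raise UrineValidationError(
                f"participant {pid}: interval with end <= start"
            )
        bad = starts[1:] < ends[:-1]
        if bad.any():
            offenders.append(str(pid))
    if offenders:
        raise UrineValidationError(
            "overlapping collection intervals for participants: "
            + ", ".join(offenders)
        )


def add_interval_amounts(
    intervals: pd.DataFrame, constants: AnalyteConstants = AnalyteConstants()
) -> pd.DataFrame:
    """Append ``volume_l``, ``hpma_umol`` and ``cema_umol`` columns.

    Expects columns ``participant, start, end, urine_weight_g,
    conc_hpma_ng_ml, conc_cema_ng_ml``.
    """
    required = {
        "participant", "start", "end", "urine_weight_g",
        "conc_hpma_ng_ml", "conc_cema_ng_ml",
    }
    missing = required - set(intervals.columns)
    if missing:
        raise UrineValidationError(f"urine table missing columns {sorted(missing)}")
    if (intervals["urine_weight_g"] < 0).any():
        raise UrineValidationError("negative urine weight in table")
    if (intervals[["conc_hpma_ng_ml", "conc_cema_ng_ml"]] < 0).any().any():
        raise UrineValidationError("negative concentration in table")
    out = intervals.copy()
    out["volume_l"] = out["urine_weight_g"] / 1000.0 / constants.urine_density
    ml = out["volume_l"] * 1000.0
    out["hpma_umol"] = out["conc_hpma_ng_ml"] * ml / constants.mw_hpma / 1000.0
    out["cema_umol"] = out["conc_cema_ng_ml"] * ml / constants.mw_cema / 1000.0
    return out


def _credit_to_windows(
    starts_h: np.ndarray,
    ends_h: np.ndarray,
    amounts: np.ndarray,
    win_start_h: float,
    win_end_h: float,
    prorate: bool,
) -> tuple[np.ndarray, np.ndarray]:
    """Amount and duration (h) of each interval credited to one window."""
    dur = ends_h - starts_h
    if prorate:
        overlap = np.clip(
            np.minimum(ends_h, win_end_h) - np.maximum(starts_h, win_start_h),
            0.0, None,
        )
        frac = np.where(dur > 0, overlap / dur, 0.0)
    else:
        mid = (starts_h + ends_h) / 2.0
        inside = (mid >= win_start_h) & (mid < win_end_h)
        overlap = np.where(inside, dur, 0.0)
        frac = inside.astype(float)
    return amounts * frac, overlap


def daily_excretion(
    intervals: pd.DataFrame,
    windows: WindowSpec = DEFAULT_WINDOWS,
    constants: AnalyteConstants = AnalyteConstants(),
    n_days: int | None = None,
) -> pd.DataFrame:
    """Per participant-day excreted amounts, umol.

    Returns one row per participant and study day with ``hpma_umol``,
    ``cema_umol``, ``sum_umol``, ``coverage_h`` (hours of the day covered
    by collections) and a ``missing`` flag for uncovered days.
    """
    _validate_no_overlap(intervals)
    amt = add_interval_amounts(intervals, constants)
    origin = _study_origin(amt, windows)
    s_h = _hours_since(amt["start"], origin)
    e_h = _hours_since(amt["end"], origin)
    hpma = amt["hpma_umol"].to_numpy()
    cema = amt["cema_umol"].to_numpy()
    pids = amt["participant"].to_numpy()

    last_day = int(np.ceil(e_h.max() / 24.0))
    if n_days is not None:
        last_day = max(last_day, n_days)
    all_pids = pd.unique(amt["participant"])

    rows = []
    for day in range(1, last_day + 1):
        w0, w1 = 24.0 * (day - 1), 24.0 * day
        c_h, ov = _credit_to_windows(s_h, e_h, hpma, w0, w1, windows.prorate)
        c_c, _ = _credit_to_windows(s_h, e_h, cema, w0, w1, windows.prorate)
        df = pd.DataFrame(
            {"participant": pids, "hpma_umol": c_h, "cema_umol": c_c, "cov": ov}
        )
        agg = df.groupby("participant", sort=False).sum()
        agg = agg.reindex(all_pids, fill_value=0.0)
        for pid, r in agg.iterrows():
            rows.append(
                {
                    "participant": pid,
                    "study_day": day,
                    "hpma_umol": r["hpma_umol"],
                    "cema_umol": r["cema_umol"],
                    "sum_umol": r["hpma_umol"] + r["cema_umol"],
                    "coverage_h": min(r["cov"], 24.0),
                    "missing": r["cov"] == 0.0,
                }
            )
    return pd.DataFrame(rows)


def overnight_excretion(
    intervals: pd.DataFrame,
    windows: WindowSpec = DEFAULT_WINDOWS,
    constants: AnalyteConstants = AnalyteConstants(),
    n_days: int | None = None,
) -> pd.DataFrame:
    """Per participant-night amounts credited to the 20:00-08:00 window.

    Each night is keyed by the *evening's* study day, so the night of day 3
    follows the day-3 dinner.  Intervals partially inside the window are
    pro-rated by duration.
    """
    _validate_no_overlap(intervals)
    amt = add_interval_amounts(intervals, constants)
    origin = _study_origin(amt, windows)
    s_h = _hours_since(amt["start"], origin)
    e_h = _hours_since(amt["end"], origin)
    hpma = amt["hpma_umol"].to_numpy()
    cema = amt["cema_umol"].to_numpy()
    pids = amt["participant"].to_numpy()

    day_h = (
        windows.day_boundary.hour + windows.day_boundary.minute / 60.0
    )
    on_start = (
        windows.overnight_start.hour + windows.overnight_start.minute / 60.0 - day_h
    ) % 24.0
    on_end = (
        windows.overnight_end.hour + windows.overnight_end.minute / 60.0 - day_h
    ) % 24.0
    if on_end <= on_start:
        on_end += 24.0

    last_day = int(np.ceil(e_h.max() / 24.0))
    if n_days is not None:
        last_day = max(last_day, n_days)
    all_pids = pd.unique(amt["participant"])

    rows = []
    for day in range(1, last_day + 1):
        w0 = 24.0 * (day - 1) + on_start
        w1 = 24.0 * (day - 1) + on_end
        c_h, ov = _credit_to_windows(s_h, e_h, hpma, w0, w1, windows.prorate)
        c_c, _ = _credit_to_windows(s_h, e_h, cema, w0, w1, windows.prorate)
        df = pd.DataFrame(
            {"participant": pids, "hpma_umol": c_h, "cema_umol": c_c, "cov": ov}
        )
        agg = df.groupby("participant", sort=False).sum()
        agg = agg.reindex(all_pids, fill_value=0.0)
        for pid, r in agg.iterrows():
            rows.append(
                {
                    "participant": pid,
                    "study_day": day,
                    "hpma_umol": r["hpma_umol"],
                    "cema_umol": r["cema_umol"],
                    "sum_umol": r["hpma_umol"] + r["cema_umol"],
                    "coverage_h": min(r["cov"], on_end - on_start),
                    "missing": r["cov"] == 0.0,
                }
            )
    return pd.DataFrame(rows)


def daily_ratio(cema_umol: float, hpma_umol: float) -> float:
    """CEMA / 3-HPMA amount ratio for one participant-day."""
    if hpma_umol <= 0:
        raise UrineValidationError(
            "daily_ratio undefined for non-positive 3-HPMA amount"
        )
    if cema_umol < 0:
        raise UrineValidationError("negative CEMA amount")
    return cema_umol / hpma_umol


def add_daily_ratios(daily: pd.DataFrame) -> pd.DataFrame:
    """Append a ``ratio`` column (NaN where 3-HPMA is zero or day missing)."""
    out = daily.copy()
    ok = (out["hpma_umol"] > 0) & ~out.get("missing", False)
    out["ratio"] = np.where(ok, out["cema_umol"] / out["hpma_umol"], np.nan)
    return out
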