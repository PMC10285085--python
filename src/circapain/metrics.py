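"""Summary measures over simulation output.

All per-day bookkeeping uses 24 h windows anchored at the simulation
origin (clock 08:00), matching the protocol day labels: day 1 is
``t`` in [0, 1440) minutes, day 2 is [1440, 2880), and so on.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd

from .protocols import MIN_PER_DAY, sim_to_clock
from .swff import TransitionEvent

__all__ = [
    "sleep_bouts",
    "daily_sleep_hours",
    "daily_pain_difference",
    "total_pain_area",
    "circadian_peak_times",
    "entrainment_day",
    "pain_peak_times",
]


def _quad_refine(t: np.ndarray, y: np.ndarray, i: int) -> float:
    """Vertex time of the parabola through samples i-1, i, i+1."""
    if i <= 0 or i >= len(t) - 1:
        return float(t[i])
    y0, y1, y2 = y[i - 1], y[i], y[i + 1]
    denom = y0 - 2.0 * y1 + y2
    if denom == 0:
        return float(t[i])
    delta = 0.5 * (y0 - y2) / denom
    delta = float(np.clip(delta, -1.0, 1.0))
    return float(t[i] + delta * (t[i + 1] - t[i]))


def _window_peaks(
    t: np.ndarray, y: np.ndarray, t0: float, window: float = MIN_PER_DAY
) -> list[float]:
    """One refined maximum time per full ``window`` starting at ``t0``."""
    t = np.asarray(t, dtype=float)
    y = np.asarray(y, dtype=float)
    peaks: list[float] = []
    step = float(np.median(np.diff(t))) if len(t) > 1 else 0.0
    n_windows = int(math.floor((t[-1] - t0 + step + 1e-9) / window))
    for d in range(n_windows):
        lo, hi = t0 + d * window, t0 + (d + 1) * window
        sel = (t >= lo - 1e-9) & (t < hi - 1e-9)
        (idx,) = np.nonzero(sel)
        if idx.size < 3:
            continue
        j = idx[np.argmax(y[idx])]
        peaks.append(_quad_refine(t, y, j))
    return peaks


def sleep_bouts(events: list[TransitionEvent], horizon: float) -> pd.DataFrame:
    """Pair sleep onsets with the following wake onsets into sleep bouts.

    A bout is attributed to the day containing its onset; a bout still open
    at the horizon is dropped.  Returns columns
    (day, start_min, end_min, duration_h, kind).
    """
    rows = []
    open_onset: float | None = None
    for ev in sorted(events, key=lambda e: e.time):
        if ev.time > horizon:
            break
        if ev.kind == "sleep_onset":
            if open_onset is not None:
                raise ValueError("two sleep onsets without an intervening wake onset")
            open_onset = ev.time
        elif ev.kind == "wake_onset":
            if open_onset is None:
                continue  # record starts mid-sleep; skip the partial bout
            rows.append(
                {
                    "day": int(math.floor(open_onset / MIN_PER_DAY)) + 1,
                    "start_min": open_onset,
                    "end_min": ev.time,
                    "duration_h": (ev.time - open_onset) / 60.0,
                    "kind": "sleep",
                }
            )
            open_onset = None
        else:
            raise ValueError(f"unknown event kind {ev.kind!r}")
    return pd.DataFrame(rows, columns=["day", "start_min", "end_min", "duration_h", "kind"])


def daily_sleep_hours(bouts: pd.DataFrame, n_days: int) -> np.ndarray:
    """Total sleep hours attributed to each of days 1..n_days."""
    out = np.zeros(n_days)
    for _, row in bouts.iterrows():
        d = int(row["day"]) - 1
        if 0 <= d < n_days:
            out[d] += row["duration_h"]
    return out


def _check_grids(t_a: np.ndarray, t_b: np.ndarray) -> None:
    if len(t_a) != len(t_b) or not np.allclose(t_a, t_b):
        raise ValueError("series must share an identical time grid")


def daily_pain_difference(
    t: np.ndarray, P_scenario: np.ndarray, P_control: np.ndarray
) -> np.ndarray:
    """Mean of (scenario - control) pain over each consecutive 24 h day."""
    t = np.asarray(t, dtype=float)
    diff = np.asarray(P_scenario, dtype=float) - np.asarray(P_control, dtype=float)
    if diff.shape != t.shape:
        raise ValueError("series must share an identical time grid")
    step = float(np.median(np.diff(t)))
    n_days = int(math.floor((t[-1] - t[0] + step + 1e-9) / MIN_PER_DAY))
    out = np.empty(n_days)
    for d in range(n_days):
        lo = t[0] + d * MIN_PER_DAY
        sel = (t >= lo - 1e-9) & (t < lo + MIN_PER_DAY - 1e-9)
        out[d] = diff[sel].mean()
    return out


def total_pain_area(
    t: np.ndarray, P_scenario: np.ndarray, P_control: np.ndarray
) -> float:
    """Trapezoid integral of the pain difference, in z-score * hours."""
    t = np.asarray(t, dtype=float)
    diff = np.asarray(P_scenario, dtype=float) - np.asarray(P_control, dtype=float)
    if diff.shape != t.shape:
        raise ValueError("series must share an identical time grid")
    return float(np.trapezoid(diff, t) / 60.0)


def circadian_peak_times(
    t: np.ndarray, Cs: np.ndarray, as_clock: bool = False
) -> np.ndarray:
    """Per-day time of the Cs maximum, quadratic-refined to < 1 min.

    Returns absolute simulation minutes (one per full day window anchored
    at ``t[0]``); with ``as_clock`` the wall-clock minutes after midnight.
    """
    Cs = np.asarray(Cs, dtype=float)
    if np.ptp(Cs) == 0:
        raise ValueError("flat series has no peak")
    peaks = np.array(_window_peaks(np.asarray(t, float), Cs, t0=float(t[0])))
    return sim_to_clock(peaks) if as_clock else peaks


def entrainment_day(
    peak_differences_h: np.ndarray, target_shift_h: float, threshold_h: float = 0.5
) -> int | None:
    """First day from which |daily peak shift - target| stays below threshold.

    ``peak_differences_h`` is the per-day absolute difference (hours)
    between the scenario's and the matched control's circadian peak times.
    Returns the 1-based day index, or None if never entrained within the
    series.
    """
    diffs = np.asarray(peak_differences_h, dtype=float)
    inside = np.abs(diffs - target_shift_h) < threshold_h
    for d in range(len(diffs)):
        if inside[d:].all():
            return d + 1
    return None


def pain_peak_times(
    t: np.ndarray, P: np.ndarray, as_clock: bool = False
) -> np.ndarray:
    """Per-day time of the total-pain maximum (same conventions as Cs peaks)."""
    P = np.asarray(P, dtype=float)
    if np.ptp(P) == 0:
        raise ValueError("flat series has no peak")
    peaks = np.array(_window_peaks(np.asarray(t, float), P, t0=float(t[0])))
    return sim_to_clock(peaks) if as_clock else peaks
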