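"""Homeostatic and circadian components of pain sensitivity.

Pain intensity is modeled as ``P(t) = Hp(t) + Cp(t)``, in z-scores of
visual-analog-scale pain ratings:

* ``Hp`` — homeostatic component: a piecewise exponential that relaxes
  toward an upper asymptote ``UA`` during wake (time constant ``tau_hw``)
  and toward a lower asymptote ``LA`` during sleep (``tau_hs``), restarting
  from its current value at every sleep/wake transition, so it is
  continuous everywhere.
* ``Cp`` — circadian component: an affine map of the circadian drive
  delayed by half a day, ``Cp(t) = gain * Cs(t - delay) + offset``.  The
  12 h delay aligns the pain maximum with the core-body-temperature minimum
  near 03:00.

The calibration pipeline (``fit_sine_24h`` / ``derive_mapping``) recovers
the affine map from fixed-period sinusoid fits of ``Cs`` and of the
experimentally identified circadian pain component.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "PainParams",
    "PainState",
    "SineFit",
    "homeostatic_pain",
    "homeostatic_pain_series",
    "circadian_pain",
    "circadian_pain_series",
    "total_pain",
    "fit_sine_24h",
    "derive_mapping",
    "load_pain_overlay",
]


@dataclass
class PainParams:
    """Pain-model constants (z-score units unless noted).

    ``UA``/``LA`` are the asymptotes of the homeostatic component; the
    homeostat time constants are shared with the sleep homeostat.
    ``map_gain``, ``map_offset`` and ``map_delay`` (minutes) define the
    affine delayed map from the circadian drive to ``Cp``.
    """

    UA: float = 0.4125
    LA: float = -0.5088
    tau_hw: float = 946.8
    tau_hs: float = 202.2
    map_gain: float = 0.3411
    map_offset: float = 0.03
    map_delay: float = 720.0

    def __post_init__(self) -> None:
        if self.UA <= self.LA:
            raise ValueError("UA must exceed LA")
        if self.map_delay < 0:
            raise ValueError("map_delay must be non-negative")
        if self.tau_hw <= 0 or self.tau_hs <= 0:
            raise ValueError("time constants must be positive")


@dataclass
class PainState:
    """Bookkeeping for the homeostatic component within one bout.

    ``H_onset`` is the value of Hp at the most recent sleep/wake
    transition, which occurred at time ``t_onset`` (minutes).
    """

    Hp: float
    H_onset: float
    t_onset: float


def homeostatic_pain(
    t: float, state: PainState, behavioral_state: str, params: PainParams
) -> float:
    """Hp at time ``t`` given the bout that started at ``state.t_onset``.

    Wake:  (H_onset - UA) exp(-(t - t_onset)/tau_hw) + UA
    Sleep: (H_onset - LA) exp(-(t - t_onset)/tau_hs) + LA
    """
    if t < state.t_onset:
        raise ValueError(f"t={t} precedes bout onset {state.t_onset}")
    dt = t - state.t_onset
    if behavioral_state == "wake":
        return (state.H_onset - params.UA) * math.exp(-dt / params.tau_hw) + params.UA
    if behavioral_state == "sleep":
        return (state.H_onset - params.LA) * math.exp(-dt / params.tau_hs) + params.LA
    raise ValueError(f"behavioral_state must be 'wake' or 'sleep', got {behavioral_state!r}")


def homeostatic_pain_series(
    t_grid: np.ndarray,
    bout_starts: np.ndarray,
    bout_awake: np.ndarray,
    hp_init: float,
    params: PainParams,
) -> np.ndarray:
    """Evaluate Hp on a grid from the bout structure, exactly (analytically).

    ``bout_starts`` are the sorted onset times (first one at or before the
    grid start), ``bout_awake`` the corresponding wake flags; ``hp_init`` is
    Hp at the first onset.  Continuity across transitions is built in: the
    onset value of each bout is the closing value of the previous one.
    """
    bout_starts = np.asarray(bout_starts, dtype=float)
    bout_awake = np.asarray(bout_awake, dtype=bool)
    n_bouts = len(bout_starts)
    onset_vals = np.empty(n_bouts)
    onset_vals[0] = hp_init
    for i in range(n_bouts - 1):
        span = bout_starts[i + 1] - bout_starts[i]
        if bout_awake[i]:
            onset_vals[i + 1] = (onset_vals[i] - params.UA) * math.exp(
                -span / params.tau_hw
            ) + params.UA
        else:
            onset_vals[i + 1] = (onset_vals[i] - params.LA) * math.exp(
                -span / params.tau_hs
            ) + params.LA
    idx = np.clip(np.searchsorted(bout_starts, t_grid, side="right") - 1, 0, n_bouts - 1)
    dt = t_grid - bout_starts[idx]
    asymp = np.where(bout_awake[idx], params.UA, params.LA)
    tau = np.where(bout_awake[idx], params.tau_hw, params.tau_hs)
    return (onset_vals[idx] - asymp) * np.exp(-dt / tau) + asymp


def circadian_pain(
    cs_history: tuple[np.ndarray, np.ndarray], t: float, params: PainParams
) -> float:
    """Cp(t) = gain * Cs(t - delay) + offset from a sampled Cs history."""
    hist_t, hist_cs = cs_history
    t_lag = t - params.map_delay
    if t_lag < hist_t[0] - 1e-9:
        raise ValueError(
            f"Cs history starts at {hist_t[0]} min; need Cs at {t_lag} min "
            "(insufficient spin-up)"
        )
    cs = float(np.interp(t_lag, hist_t, hist_cs))
    return params.map_gain * cs + params.map_offset


def circadian_pain_series(
    t_grid: np.ndarray, Cs: np.ndarray, params: PainParams
) -> np.ndarray:
    """Vectorized Cp on the grid carrying its own Cs history.

    Lags reaching before the start of the grid clamp to the first sample;
    they can only occur inside the spin-up period, which is discarded.
    """
    return params.map_gain * np.interp(
        t_grid - params.map_delay, t_grid, Cs
    ) + params.map_offset


def total_pain(Hp, Cp):
    """Total pain intensity P = Hp + Cp (exact sum, any array-likes)."""
    return np.asarray(Hp) + np.asarray(Cp)


@dataclass(frozen=True)
class SineFit:
    """A fixed-period sinusoid ``A sin(2 pi / period (t - phase)) + offset``.

    Canonical form: ``amplitude >= 0`` and ``phase`` in [0, period).
    """

    amplitude: float
    phase: float
    offset: float
    period: float = 1440.0

    def __call__(self, t):
        w = 2.0 * math.pi / self.period
        return self.amplitude * np.sin(w * (np.asarray(t, dtype=float) - self.phase)) + self.offset


def fit_sine_24h(t, values, period: float = 1440.0) -> SineFit:
    """Least-squares fit of a fixed-period (default 24 h) sinusoid.

    With the period fixed the problem is linear: fit
    ``a sin(wt) + b cos(wt) + m`` and convert, avoiding nonlinear phase
    optimization entirely.  A flat series yields amplitude 0 with phase 0
    by convention.
    """
    t = np.asarray(t, dtype=float)
    y = np.asarray(values, dtype=float)
    if t.size < 4:
        raise ValueError("need at least 4 samples for a 3-parameter fit")
    if np.ptp(t) < period:
        raise ValueError("need at least one full period of samples")
    w = 2.0 * math.pi / period
    design = np.column_stack([np.sin(w * t), np.cos(w * t), np.ones_like(t)])
    (a, b, m), *_ = np.linalg.lstsq(design, y, rcond=None)
    amplitude = math.hypot(a, b)
    if amplitude < 1e-12:
        return SineFit(0.0, 0.0, float(m), period)
    # a sin(wt) + b cos(wt) = A sin(w(t - phi)) with a = A cos(w phi), b = -A sin(w phi)
    phase = (-math.atan2(b, a) / w) % period
    return SineFit(float(amplitude), float(phase), float(m), period)


def derive_mapping(cs_fit: SineFit, cp_fit: SineFit) -> tuple[float, float, float]:
    """Affine map (gain, offset, delay) sending the Cs fit onto the Cp fit.

    ``gain`` matches the amplitudes, ``offset`` the midlines.  The delay is
    fixed at 720 min (half a day): experimentally both the pain-sensitivity
    maximum and the core-body-temperature minimum — i.e. the Cs minimum —
    fall near 03:00, so the map inverts the rhythm by a 12 h shift rather
    than by the difference of the fitted phases.
    """
    if cs_fit.period != cp_fit.period:
        raise ValueError("fits must share a period")
    if cs_fit.amplitude == 0:
        raise ValueError("degenerate mapping: Cs fit has zero amplitude")
    gain = cp_fit.amplitude / cs_fit.amplitude
    offset = cp_fit.offset - gain * cs_fit.offset
    return gain, offset, 720.0


def load_pain_overlay(path: str | Path) -> pd.DataFrame:
    """Load a two-column (time_min, z_score) CSV of digitized pain points.

    Intended for overlaying experimental measurements on model output; the
    package carries no such data and nothing depends on its presence.
    """
    df = pd.read_csv(path)
    if df.shape[1] < 2:
        raise ValueError("overlay CSV needs two columns: time_min, z_score")
    df = df.iloc[:, :2]
    df.columns = ["time_min", "z_score"]
    return df
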