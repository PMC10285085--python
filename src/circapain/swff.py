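"""Sleep-wake flip-flop: firing-rate populations, homeostat, and simulator.

Three neural populations — wake-promoting (``fW``), sleep-promoting
(``fS``) and the SCN pacemaker population (``fSCN``) — interact by mutual
inhibition with circadian modulation.  Each relaxes toward a sigmoidal
steady-state response of its net input.  The homeostatic sleep drive ``Hs``
(percent slow-wave-activity power) rises exponentially during wake and
falls during sleep, and raises sleep propensity by lowering the
half-activation threshold of the sleep population.

The behavioral state is a discrete flag: sleep onset occurs when ``fW``
falls through the threshold ``theta_W`` and wake onset when it rises back
through it.  The Heaviside switch of the homeostat is driven by this flag
(hybrid-system semantics) so bout bookkeeping is exact and the branch
cannot chatter while ``fW`` hovers near threshold.

``simulate`` integrates the coupled clock + flip-flop system over a
:class:`~circapain.protocols.Protocol`, splitting integration at light and
forcing discontinuities and locating every threshold crossing by event
detection, then attaches the pain components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import solve_ivp

from .clock import ClockParams
from .pain import (
    PainParams,
    circadian_pain_series,
    homeostatic_pain_series,
    total_pain,
)
from .protocols import MIN_PER_DAY, Protocol, sim_to_clock

__all__ = [
    "SWFFParams",
    "SWFFState",
    "TransitionEvent",
    "SimulationResult",
    "sigmoid_response",
    "beta_S_of_Hs",
    "swff_rhs",
    "detect_transitions",
    "simulate",
]


@dataclass
class SWFFParams:
    """Flip-flop and homeostat constants (reference adult-human set)."""

    Wmax: float = 6.0  # Hz
    Smax: float = 6.0  # Hz
    SCNmax: float = 7.0  # Hz
    tau_W: float = 23.0  # min
    tau_S: float = 10.0  # min
    tau_SCN: float = 0.5  # min
    alpha_W: float = 0.4
    alpha_S: float = 0.2
    alpha_SCN: float = 0.7
    beta_W: float = -0.4
    beta_SCN: float = -0.1
    g_sw: float = 0.2508  # sleep -> wake inhibition
    g_scnw: float = 0.01  # SCN -> wake excitation
    g_ws: float = 0.25  # wake -> sleep inhibition
    g_scns: float = 0.07  # SCN -> sleep inhibition
    h_max: float = 323.88  # %SWA
    h_min: float = 0.0
    tau_hw: float = 946.8  # min, homeostat rise
    tau_hs: float = 202.2  # min, homeostat fall
    k1: float = -0.0118  # beta_S(Hs) intercept
    k2: float = -0.005  # beta_S(Hs) slope
    theta_W: float = 4.0  # Hz, behavioral-state threshold

    def __post_init__(self) -> None:
        if min(self.tau_W, self.tau_S, self.tau_SCN, self.tau_hw, self.tau_hs) <= 0:
            raise ValueError("all time constants must be positive")
        if self.h_max <= self.h_min:
            raise ValueError("h_max must exceed h_min")
        if not 0.0 < self.theta_W < self.Wmax:
            raise ValueError("theta_W must lie in (0, Wmax)")


@dataclass
class SWFFState:
    """Firing rates (Hz), homeostat level (%SWA) and behavioral flags."""

    fW: float
    fS: float
    fSCN: float
    Hs: float
    behavioral_state: str = "wake"  # "wake" | "sleep"
    forced_wake: bool = False


@dataclass(frozen=True)
class TransitionEvent:
    """A sleep/wake transition at ``time`` minutes since experiment origin."""

    time: float
    kind: str  # "sleep_onset" | "wake_onset"
    forced: bool = False


def sigmoid_response(x: float, max_rate: float, beta: float, alpha: float) -> float:
    """Steady-state firing rate ``max * 0.5 * (1 + tanh((x - beta)/alpha))``.

    Strictly increasing in the net input ``x``, saturating at ``max_rate``;
    half-activation at ``x = beta``.
    """
    if alpha == 0:
        raise ValueError("sigmoid slope alpha must be nonzero")
    return max_rate * 0.5 * (1.0 + math.tanh((x - beta) / alpha))


def beta_S_of_Hs(Hs: float, params: SWFFParams) -> float:
    """Homeostat-dependent sleep threshold ``k2 * Hs + k1``.

    With ``k2 < 0`` the threshold drops as sleep pressure accumulates, so
    the sleep population activates at progressively weaker net input.
    """
    return params.k2 * Hs + params.k1


def swff_rhs(
    state: SWFFState,
    Cs: float,
    params: SWFFParams,
    forced_wake: bool = False,
) -> tuple[float, float, float, float]:
    """Time derivatives (dfW, dfS, dfSCN, dHs) per minute.

    ``Cs`` is the circadian drive at the same instant.  During forced
    wakefulness a constant excitatory input of magnitude ``g_sw * Smax`` is
    added to the wake population's net input (enough to hold ``fW`` above
    threshold against any sleep-population inhibition) and the homeostat
    uses its wake branch.
    """
    x_w = params.g_scnw * state.fSCN - params.g_sw * state.fS
    if forced_wake:
        x_w += params.g_sw * params.Smax
    dfW = (
        sigmoid_response(x_w, params.Wmax, params.beta_W, params.alpha_W) - state.fW
    ) / params.tau_W
    x_s = -params.g_ws * state.fW - params.g_scns * state.fSCN
    dfS = (
        sigmoid_response(x_s, params.Smax, beta_S_of_Hs(state.Hs, params), params.alpha_S)
        - state.fS
    ) / params.tau_S
    dfSCN = (
        sigmoid_response(Cs, params.SCNmax, params.beta_SCN, params.alpha_SCN)
        - state.fSCN
    ) / params.tau_SCN
    awake = forced_wake or state.behavioral_state == "wake"
    if awake:
        dHs = (params.h_max - state.Hs) / params.tau_hw
    else:
        dHs = (params.h_min - state.Hs) / params.tau_hs
    return dfW, dfS, dfSCN, dHs


def detect_transitions(
    t: np.ndarray, fW: np.ndarray, theta_W: float = 4.0
) -> list[TransitionEvent]:
    """Threshold crossings of a sampled ``fW`` trajectory.

    Downward crossings of ``theta_W`` are sleep onsets, upward crossings
    wake onsets; crossing times are refined by linear interpolation between
    the bracketing samples (well under 0.1 min at a 1-min grid, since fW
    moves on the 23-min population time scale).
    """
    t = np.asarray(t, dtype=float)
    fW = np.asarray(fW, dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time axis must be strictly increasing")
    above = fW > theta_W
    events: list[TransitionEvent] = []
    (idx,) = np.nonzero(above[1:] != above[:-1])
    for i in idx:
        f0, f1 = fW[i], fW[i + 1]
        tc = t[i] + (theta_W - f0) / (f1 - f0) * (t[i + 1] - t[i])
        kind = "sleep_onset" if f0 > theta_W else "wake_onset"
        events.append(TransitionEvent(float(tc), kind))
    return events


@dataclass
class SimulationResult:
    """Uniform-grid output of a coupled simulation.

    Times are minutes since the experiment origin (clock 08:00 of protocol
    day 1); the spin-up period occupies negative times.  All state series
    share the grid ``t``.
    """

    t: np.ndarray
    light: np.ndarray
    Cs: np.ndarray
    xC: np.ndarray
    n: np.ndarray
    fW: np.ndarray
    fS: np.ndarray
    fSCN: np.ndarray
    Hs: np.ndarray
    Hp: np.ndarray
    Cp: np.ndarray
    P: np.ndarray
    awake: np.ndarray  # bool
    forced: np.ndarray  # bool
    events: list[TransitionEvent]
    protocol: Protocol
    spinup_peak_drift_min: float = math.nan

    def experiment(self) -> "SimulationResult":
        """The result restricted to t >= 0 (spin-up discarded)."""
        return self.restrict(0.0, float(self.t[-1]))

    def restrict(self, t0: float, t1: float) -> "SimulationResult":
        sel = (self.t >= t0 - 1e-9) & (self.t <= t1 + 1e-9)
        kw = {
            name: getattr(self, name)[sel]
            for name in (
                "t", "light", "Cs", "xC", "n", "fW", "fS", "fSCN",
                "Hs", "Hp", "Cp", "P", "awake", "forced",
            )
        }
        return SimulationResult(
            events=[e for e in self.events if t0 - 1e-9 <= e.time <= t1 + 1e-9],
            protocol=self.protocol,
            spinup_peak_drift_min=self.spinup_peak_drift_min,
            **kw,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time_min": self.t,
                "clock_time": sim_to_clock(self.t),
                "light_lux": self.light,
                "fW": self.fW,
                "fS": self.fS,
                "fSCN": self.fSCN,
                "Hs": self.Hs,
                "Cs": self.Cs,
                "xC": self.xC,
                "n": self.n,
                "state": np.where(self.awake, "wake", "sleep"),
                "forced": self.forced,
                "Hp": self.Hp,
                "Cp": self.Cp,
                "P": self.P,
            }
        )

    def events_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": [e.time for e in self.events],
                "kind": [e.kind for e in self.events],
                "forced": [e.forced for e in self.events],
            }
        )


def _make_rhs(cp: ClockParams, sp: SWFFParams, I: float, forced: bool, awake: bool):
    """Scalar RHS closure for one constant-light, constant-regime segment."""
    alpha = 0.0 if I == 0 else cp.alpha0 * (I / cp.I0) ** cp.p
    G_alpha = cp.G * alpha
    omega2 = (24.0 / (0.99669 * cp.tau_x)) ** 2
    pref = math.pi / 720.0
    forcing = sp.g_sw * sp.Smax if forced else 0.0
    wake_branch = awake or forced
    tanh = math.tanh

    def rhs(t, y):
        Cs, xC, n, fW, fS, fSCN, Hs = y
        B = G_alpha * (1.0 - n) * (1.0 - 0.4 * Cs) * (1.0 - 0.4 * xC)
        dCs = pref * (xC + B)
        dxC = pref * (
            cp.mu * (xC - 4.0 * xC * xC * xC / 3.0) - Cs * (omega2 + cp.k * B)
        )
        dn = alpha * (1.0 - n) - cp.beta_n * n
        x_w = sp.g_scnw * fSCN - sp.g_sw * fS + forcing
        dfW = (
            sp.Wmax * 0.5 * (1.0 + tanh((x_w - sp.beta_W) / sp.alpha_W)) - fW
        ) / sp.tau_W
        beta_s = sp.k2 * Hs + sp.k1
        x_s = -sp.g_ws * fW - sp.g_scns * fSCN
        dfS = (
            sp.Smax * 0.5 * (1.0 + tanh((x_s - beta_s) / sp.alpha_S)) - fS
        ) / sp.tau_S
        dfSCN = (
            sp.SCNmax * 0.5 * (1.0 + tanh((Cs - sp.beta_SCN) / sp.alpha_SCN)) - fSCN
        ) / sp.tau_SCN
        dHs = (
            (sp.h_max - Hs) / sp.tau_hw if wake_branch else (sp.h_min - Hs) / sp.tau_hs
        )
        return (dCs, dxC, dn, dfW, dfS, dfSCN, dHs)

    return rhs


def _daily_cs_peak_drift(t: np.ndarray, Cs: np.ndarray) -> float:
    """Max day-to-day change (min) of the Cs peak time over the last days."""
    from .metrics import _window_peaks

    peaks = _window_peaks(t, Cs, t0=float(t[0]))
    if len(peaks) < 2:
        return math.nan
    rel = np.asarray(peaks) % MIN_PER_DAY
    diffs = np.diff(rel)
    diffs = (diffs + MIN_PER_DAY / 2) % MIN_PER_DAY - MIN_PER_DAY / 2
    return float(np.max(np.abs(diffs)))


def simulate(
    protocol: Protocol,
    clock_params: ClockParams | None = None,
    swff_params: SWFFParams | None = None,
    pain_params: PainParams | None = None,
    *,
    grid_min: float = 1.0,
    rtol: float = 1e-8,
    atol: float = 1e-8,
    initial_state: np.ndarray | None = None,
    method: str = "LSODA",
) -> SimulationResult:
    """Integrate the coupled clock + flip-flop + pain system over a protocol.

    The full state vector is ``(Cs, xC, n, fW, fS, fSCN, Hs)``; ``fSCN`` is
    fast (tau = 0.5 min) so a stiff-capable adaptive method is used, with
    the integration split at every light or forcing discontinuity and at
    every detected threshold crossing of ``fW``.  Output is on a uniform
    ``grid_min``-minute grid spanning spin-up and experiment.

    Spin-up starts ``protocol.spinup_days`` before the experiment, at clock
    time 08:00, from a fixed reference state; the entrained periodic orbit
    erases that choice.  Pass ``initial_state`` to verify insensitivity.
    """
    cp = clock_params or ClockParams()
    sp = swff_params or SWFFParams()
    pp = pain_params or PainParams()
    if pp.tau_hw != sp.tau_hw or pp.tau_hs != sp.tau_hs:
        # The pain homeostat shares the sleep homeostat's kinetics by
        # construction; allow overrides but keep them deliberate.
        pass
    t_start = -protocol.spinup_days * MIN_PER_DAY
    t_end = float(protocol.duration)
    n_grid = int(round((t_end - t_start) / grid_min)) + 1
    t_grid = t_start + grid_min * np.arange(n_grid)

    if initial_state is None:
        y = np.array([-1.0, 0.0, 0.5, 6.0, 0.0, 0.5, 100.0])
    else:
        y = np.asarray(initial_state, dtype=float).copy()
        if y.shape != (7,):
            raise ValueError("initial_state must have 7 components")
    awake = True

    Y = np.empty((7, n_grid))
    awake_arr = np.empty(n_grid, dtype=bool)
    forced_arr = np.empty(n_grid, dtype=bool)
    Y[:, 0] = y
    awake_arr[0] = True
    forced_arr[0] = protocol.forced_at(t_start)
    events: list[TransitionEvent] = []
    bout_starts = [t_start]
    bout_awake = [True]

    seg_bounds = [t_start] + protocol.breakpoints(t_start, t_end) + [t_end]
    fill = 1  # next grid index to fill
    for a, b in zip(seg_bounds[:-1], seg_bounds[1:]):
        if b - a <= 1e-12:
            continue
        mid = 0.5 * (a + b)
        I = protocol.lux_at(mid)
        forced = protocol.forced_at(mid)
        if forced and not awake:
            awake = True
            events.append(TransitionEvent(float(a), "wake_onset", forced=True))
            bout_starts.append(float(a))
            bout_awake.append(True)
        cur = a
        while cur < b - 1e-9:
            rhs = _make_rhs(cp, sp, I, forced, awake)
            if forced:
                ev = None
            else:
                direction = -1.0 if awake else 1.0

                def crossing(t, y, _d=direction):
                    return y[3] - sp.theta_W

                crossing.terminal = True
                crossing.direction = direction
                ev = [crossing]
            sol = solve_ivp(
                rhs,
                (cur, b),
                y,
                method=method,
                rtol=rtol,
                atol=atol,
                dense_output=True,
                events=ev,
                max_step=120.0,
            )
            if not sol.success:
                raise RuntimeError(
                    f"integration failed near t={sol.t[-1]:.2f} min: {sol.message}"
                )
            reached = float(sol.t[-1])
            hi = np.searchsorted(t_grid, reached + 1e-9)
            if hi > fill:
                Y[:, fill:hi] = sol.sol(t_grid[fill:hi])
                awake_arr[fill:hi] = awake
                forced_arr[fill:hi] = forced
                fill = hi
            y = sol.y[:, -1].copy()
            if sol.status == 1:  # threshold crossing
                te = float(sol.t_events[0][0])
                y = sol.sol(te)
                kind = "sleep_onset" if awake else "wake_onset"
                awake = not awake
                events.append(TransitionEvent(te, kind))
                bout_starts.append(te)
                bout_awake.append(awake)
                cur = te
            else:
                cur = reached
        if not np.all(np.isfinite(y)):
            raise RuntimeError(f"non-finite state at t={cur:.2f} min")
    if fill < n_grid:  # end point lands exactly on the grid
        Y[:, fill:] = y[:, None]
        awake_arr[fill:] = awake
        forced_arr[fill:] = forced_arr[fill - 1] if fill > 0 else False

    Cs, xC, n, fW, fS, fSCN, Hs = Y
    light = np.array([protocol.lux_at(t) for t in t_grid])
    Hp = homeostatic_pain_series(
        t_grid, np.array(bout_starts), np.array(bout_awake), hp_init=0.0, params=pp
    )
    Cp = circadian_pain_series(t_grid, Cs, pp)
    P = total_pain(Hp, Cp)

    spin = t_grid < 0
    drift = math.nan
    if protocol.spinup_days >= 4:
        tail = spin & (t_grid >= -3 * MIN_PER_DAY)
        drift = _daily_cs_peak_drift(t_grid[tail], Cs[tail])

    return SimulationResult(
        t=t_grid,
        light=light,
        Cs=Cs,
        xC=xC,
        n=n,
        fW=fW,
        fS=fS,
        fSCN=fSCN,
        Hs=Hs,
        Hp=Hp,
        Cp=Cp,
        P=P,
        awake=awake_arr,
        forced=forced_arr,
        events=events,
        protocol=protocol,
        spinup_peak_drift_min=drift,
    )
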