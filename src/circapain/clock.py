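"""Light-sensitive circadian pacemaker.

A modified Van der Pol oscillator whose primary variable ``Cs`` tracks the
24 h rhythm of human circadian markers (the minimum of ``Cs`` corresponds to
the core-body-temperature minimum).  Environmental illuminance enters through
a photic process: a pool of light-responsive elements with activated
fraction ``n`` converts lux into the entraining drive ``B``.

Time is measured in minutes throughout; the intrinsic period ``tau_x`` is
stored in hours, as conventionally printed, and converted inside the
right-hand side.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

__all__ = [
    "ClockParams",
    "ClockState",
    "photic_alpha",
    "photic_n_rate",
    "light_drive",
    "clock_rhs",
]


class ProtocolError(ValueError):
    """Invalid protocol input (e.g. negative illuminance)."""


class StateError(ValueError):
    """Dynamical state outside its physical domain."""


@dataclass
class ClockParams:
    """Constants of the circadian oscillator and its photic process.

    Parameters
    ----------
    mu : float
        Stiffness of the oscillator (unitless).
    tau_x : float
        Intrinsic period of the oscillator, in hours.
    k : float
        Modulation of the light effect on the oscillator (unitless).
    G : float
        Photic gain (unitless).
    I0 : float
        Reference illuminance, in lux.
    alpha0 : float
        Photic activation rate at the reference illuminance, per minute.
    p : float
        Illuminance exponent (compressive, in (0, 1]).
    beta_n : float
        Photic recovery rate, per minute.
    """

    mu: float = 0.23
    tau_x: float = 24.2
    k: float = 0.55
    G: float = 33.75
    I0: float = 9500.0
    alpha0: float = 0.05
    p: float = 0.5
    beta_n: float = 0.0075

    def __post_init__(self) -> None:
        if self.mu <= 0 or self.tau_x <= 0 or self.I0 <= 0:
            raise ValueError("mu, tau_x and I0 must be strictly positive")
        if self.alpha0 <= 0 or self.beta_n <= 0:
            raise ValueError("photic rates must be strictly positive")
        if not 0.0 < self.p <= 1.0:
            raise ValueError("illuminance exponent p must lie in (0, 1]")


@dataclass
class ClockState:
    """Instantaneous state of the pacemaker.

    ``Cs`` is the circadian drive (approximately in [-1.1, 1.1] on the limit
    cycle), ``xC`` its complementary oscillator variable, and ``n`` the
    fraction of activated photic elements (in [0, 1]).
    """

    Cs: float
    xC: float
    n: float

    def validate(self) -> None:
        if not (math.isfinite(self.Cs) and math.isfinite(self.xC)):
            raise StateError("Cs and xC must be finite")
        if not -1e-9 <= self.n <= 1.0 + 1e-9:
            raise StateError(f"photic fraction n={self.n} outside [0, 1]")


def photic_alpha(I: float, params: ClockParams) -> float:
    """Photic activation rate alpha(I) = alpha0 * (I / I0)**p, per minute.

    Zero light gives zero activation; negative illuminance is rejected.
    """
    if I < 0:
        raise ProtocolError(f"illuminance must be non-negative, got {I}")
    if I == 0:
        return 0.0
    return params.alpha0 * (I / params.I0) ** params.p


def photic_n_rate(n: float, I: float, params: ClockParams) -> float:
    """dn/dt for the activated photic fraction: alpha(I)(1-n) - beta*n.

    The steady state n* = alpha / (alpha + beta) always lies in [0, 1], so
    the dynamics keep ``n`` in the unit interval.
    """
    if not -1e-9 <= n <= 1.0 + 1e-9:
        raise StateError(f"photic fraction n={n} outside [0, 1]")
    return photic_alpha(I, params) * (1.0 - n) - params.beta_n * n


def light_drive(state: ClockState, I: float, params: ClockParams) -> float:
    """Entraining drive B = G(1-n)alpha(I) * (1-0.4 Cs)(1-0.4 xC).

    The multiplicative terms implement circadian gating of light
    sensitivity: the same lux has a different effect depending on the
    oscillator's phase.
    """
    state.validate()
    b_hat = params.G * (1.0 - state.n) * photic_alpha(I, params)
    return b_hat * (1.0 - 0.4 * state.Cs) * (1.0 - 0.4 * state.xC)


def clock_rhs(
    state: ClockState, I: float, params: ClockParams
) -> tuple[float, float]:
    """Time derivatives (dCs/dt, dxC/dt) in 1/min.

    dCs/dt = (pi/720) (xC + B)
    dxC/dt = (pi/720) [mu (xC - 4 xC^3 / 3)
                       - Cs ((24 / (0.99669 tau_x))^2 + k B)]

    with ``tau_x`` in hours.  The 0.99669 factor is the standard correction
    making the realized limit-cycle period equal tau_x.
    """
    B = light_drive(state, I, params)
    pref = math.pi / 720.0
    dCs = pref * (state.xC + B)
    omega2 = (24.0 / (0.99669 * params.tau_x)) ** 2
    dxC = pref * (
        params.mu * (state.xC - 4.0 * state.xC**3 / 3.0)
        - state.Cs * (omega2 + params.k * B)
    )
    return dCs, dxC
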