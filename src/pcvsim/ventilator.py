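"""Pressure-controlled ventilation (PCV) output waveform.

In PCV the ventilator drives a prescribed pressure at the airway opening and
flow/volume follow from the respiratory mechanics. The waveform is the ideal
trapezoid: a linear rise from EPAP to IPAP over the rise time Tr, a plateau at
IPAP until the end of the inspiratory time Ti, a symmetric linear fall back to
EPAP over Tr, then EPAP until the cycle ends at 60/BPM seconds. Each cycle
starts at the beginning of the inspiratory rise; inspiration is the window
[0, Ti], expiration (Ti, period].
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["VentilatorSettings", "cycle_period", "pcv_pressure"]


@dataclass(frozen=True)
class VentilatorSettings:
    """PCV settings: pressures in cmH2O gauge, times in seconds.

    Defaults are the prototype operating point: IPAP 22, EPAP 4, 20 breaths
    per minute, Ti 1 s, Tr 0.2 s.
    """

    ipap: float = 22.0
    epap: float = 4.0
    bpm: float = 20.0
    ti: float = 1.0
    tr: float = 0.2

    def __post_init__(self) -> None:
        if not self.ipap > self.epap >= 0.0:
            raise ValueError("require IPAP > EPAP >= 0 (cmH2O gauge)")
        if self.bpm <= 0.0:
            raise ValueError("breaths per minute must be positive")
        period = 60.0 / self.bpm
        if not 0.0 < self.tr < self.ti < period:
            raise ValueError("require 0 < Tr < Ti < 60/BPM")
        if self.ti + self.tr > period:
            raise ValueError("expiratory fall (Ti + Tr) does not fit the cycle")

    @property
    def period(self) -> float:
        return cycle_period(self)


def cycle_period(settings: VentilatorSettings) -> float:
    """Breath period 60/BPM in seconds; BPM sets only the cycle length."""
    return 60.0 / settings.bpm


def pcv_pressure(settings: VentilatorSettings, t):
    """Ventilator output pressure (cmH2O gauge) at time(s) ``t``.

    Piecewise-linear, continuous, periodic with period 60/BPM; accepts a
    scalar or an array and returns the matching shape.
    """
    s = settings
    period = cycle_period(s)
    tau = np.mod(np.asarray(t, dtype=float), period)
    knots_t = np.array([0.0, s.tr, s.ti, s.ti + s.tr, period])
    knots_p = np.array([s.epap, s.ipap, s.ipap, s.epap, s.epap])
    out = np.interp(tau, knots_t, knots_p)
    if np.isscalar(t) or np.ndim(t) == 0:
        return float(out)
    return out
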