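"""Isothermal variable-volume lung: pressure dynamics and compliance.

The lung (a passive test-lung bellows) is a single compartment of compliance
C = dV/dp whose gas obeys pV = mRT at constant ambient temperature. Mass
balance d(pV)/dt = RT q together with dV = C dp gives the pressure equation

    dp/dt = R T q V / (V^2 + C m R T)  =  R T q / (V + C p)   (m = pV/RT),

so the state reduces to the single pressure p, with V affine in p.

Compliance estimation inverts the same mass balance over an inspiration:
rho_std * RT * int(Q dt) = Delta(pV) = Delta_p * (V_start + C * p_end), hence

    C = (rho_std * R * T * int(Q dt) / Delta_p  -  V_start) / p_end.

As V_start -> 0 and p_end -> rho_std*R*T this reduces to the familiar
tidal-volume-over-pressure-swing ratio int(Q dt)/Delta_p; at realistic resting
volumes the two correction factors matter (the inhaled gas also compresses the
gas already resident in the lung), which is why the exact inversion is used.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .gas_flow import GasProperties
from .units import M3_PER_ML, PA_PER_CMH2O, gauge_to_abs

__all__ = [
    "LungState",
    "DegenerateTraceError",
    "pressure_derivative",
    "volume_update",
    "estimate_compliance",
]


class DegenerateTraceError(ValueError):
    """Raised when a trace carries no usable pressure swing."""


@dataclass(frozen=True)
class LungState:
    """Lung gas state: absolute pressure p (Pa), volume V (m3), compliance C
    (m3/Pa) and gas mass m (kg), maintained consistent with m = pV/(RT)."""

    p: float
    V: float
    C: float
    m: float

    def __post_init__(self) -> None:
        if self.p <= 0.0 or self.V <= 0.0 or self.C <= 0.0:
            raise ValueError("pressure, volume and compliance must be positive")

    @classmethod
    def create(
        cls, p: float, V: float, C: float, gas: GasProperties | None = None
    ) -> "LungState":
        gas = gas or GasProperties()
        return cls(p=p, V=V, C=C, m=p * V / (gas.R_specific * gas.T))

    def advanced(self, dp: float, gas: GasProperties) -> "LungState":
        """State after a pressure increment dp, with dV = C dp and m = pV/RT."""
        p = self.p + dp
        V = self.V + volume_update(self, dp)
        return replace(self, p=p, V=V, m=p * V / (gas.R_specific * gas.T))


def pressure_derivative(state: LungState, gas: GasProperties, q: float) -> float:
    """dp/dt = R T q V / (V^2 + C m R T) for signed mass inflow q (Pa/s)."""
    RT = gas.R_specific * gas.T
    return RT * q * state.V / (state.V**2 + state.C * state.m * RT)


def volume_update(state: LungState, dp: float) -> float:
    """Volume increment dV = C dp for a pressure increment dp."""
    return state.C * dp


def estimate_compliance(
    trace,
    v0: float | None = None,
    gas: GasProperties | None = None,
    settings=None,
    min_swing_cmh2o: float = 0.5,
) -> float:
    """Estimate compliance (mL/cmH2O) from a pressure/flow trace.

    Applies the isothermal mass-balance inversion per post-transient cycle,
    using the inspiratory window [cycle start, cycle start + Ti], and averages
    over cycles. ``trace`` needs arrays ``t`` (s), ``p_lung`` (cmH2O gauge)
    and ``Q`` (L/s) plus a ``config`` carrying the ventilator settings;
    synthetic recordings from :mod:`pcvsim.io_cli` qualify.

    Parameters
    ----------
    v0 : resting lung volume at the start of inspiration (m3). Defaults to
        the value recorded on ``trace.config``, else 1.0 L.
    min_swing_cmh2o : inspiration windows with a smaller lung-pressure swing
        are rejected as degenerate.
    """
    cfg = getattr(trace, "config", None)
    if settings is None:
        if cfg is None:
            raise ValueError("trace carries no config; pass settings explicitly")
        settings = cfg.settings
    gas = gas or (cfg.gas if cfg is not None else GasProperties())
    if v0 is None:
        v0 = cfg.V0 if cfg is not None else 1.0e-3
    period = settings.period
    ti = settings.ti
    t = np.asarray(trace.t, dtype=float)
    p_abs = gauge_to_abs(np.asarray(trace.p_lung, dtype=float), gas.p_atm)
    Q = np.asarray(trace.Q, dtype=float) * 1e-3  # L/s -> m3/s

    discard = cfg.discard_cycles if cfg is not None else 0
    n_cycles = int(np.floor((t[-1] - t[0]) / period + 1e-9))
    estimates = []
    for k in range(discard, n_cycles):
        start, end = t[0] + k * period, t[0] + k * period + ti
        sel = (t >= start - 1e-12) & (t <= end + 1e-12)
        if sel.sum() < 2:
            continue
        dp = p_abs[sel][-1] - p_abs[sel][0]
        if abs(dp) < min_swing_cmh2o * PA_PER_CMH2O:
            continue
        inhaled = np.trapezoid(Q[sel], t[sel])  # standard-state volume, m3
        c_si = (gas.rho_std * gas.R_specific * gas.T * inhaled / dp - v0) / p_abs[
            sel
        ][-1]
        estimates.append(c_si)
    if not estimates:
        raise DegenerateTraceError(
            "no complete inspiration with a usable pressure swing in trace"
        )
    c_si = float(np.mean(estimates))
    if c_si <= 0.0:
        raise DegenerateTraceError("estimated compliance is non-positive")
    return c_si * PA_PER_CMH2O / M3_PER_ML
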