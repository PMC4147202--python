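"""Compressible orifice flow and Reynolds-dependent airway resistance.

The ventilation circuit (ventilator - tube - airway - lung) is lumped into a
single equivalent orifice of diameter ``d`` and length ``l``. Air crossing the
orifice follows the converging-nozzle (Laval) mass-flow law; in the pressure
range of ventilation (a few tens of cmH2O above atmosphere) the flow is always
subsonic and the exact law is well approximated by the standard-state form

    q = 0.0048 * ni * Ae * pu * sqrt(phi * (1 - phi)),   phi = pd / pu

with ``q`` in kg/s, ``Ae`` in m2 and pressures in Pa absolute. The respiratory
resistance is the Darcy friction drop of the orifice,

    Rr = 8 * lam * l * q / (pi^2 * d^5),

with the friction coefficient ``lam`` taken from a three-branch piecewise fit
of the Moody chart (laminar 64/Re below Re=2000, transitional to Re=3000,
weakly turbulent above). In the laminar branch Rr reduces algebraically to the
Poiseuille resistance 128*mu*l/(pi*d^4), which is also the q -> 0 limit.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

from .units import PA_S_M3_PER_CMH2O_L_S

__all__ = [
    "GasProperties",
    "ThrottleGeometry",
    "FlowState",
    "ResistanceState",
    "critical_pressure_ratio",
    "mass_flow_exact",
    "mass_flow_simplified",
    "volume_flow",
    "reynolds_number",
    "friction_coefficient",
    "resistance",
    "laminar_resistance",
    "pressure_loss",
    "throttle_flow",
    "resistance_state",
    "SIMPLIFIED_FLOW_COEFF",
]

#: Coefficient of the standard-state mass-flow approximation (SI units).
SIMPLIFIED_FLOW_COEFF = 0.0048


@dataclass(frozen=True)
class GasProperties:
    """Physical constants of the working gas (air at ambient temperature).

    Parameters
    ----------
    kappa : adiabatic index (dimensionless), > 1.
    R_specific : specific gas constant (J kg-1 K-1).
    T : absolute temperature (K); the circuit is isothermal at ambient T.
    mu : dynamic viscosity (Pa s).
    rho_std : standard-state density (kg m-3); fixed by the 0.004/0.0048
        coefficient ratio between volume and mass flow.
    p_atm : atmospheric reference pressure (Pa, absolute).
    """

    kappa: float = 1.4
    R_specific: float = 287.0
    T: float = 293.15
    mu: float = 1.82e-5
    rho_std: float = 1.2
    p_atm: float = 101325.0

    def __post_init__(self) -> None:
        if self.kappa <= 1.0:
            raise ValueError(f"adiabatic index must exceed 1, got {self.kappa}")
        for name in ("R_specific", "T", "mu", "rho_std", "p_atm"):
            if getattr(self, name) <= 0.0:
                raise ValueError(f"{name} must be positive")

    @property
    def b(self) -> float:
        """Critical (choking) pressure ratio for this gas."""
        return critical_pressure_ratio(self)


@dataclass(frozen=True)
class ThrottleGeometry:
    """Equivalent orifice lumping tube + airway: diameter d and length l (m)."""

    d: float = 3.2e-3
    l: float = 10.0e-3

    def __post_init__(self) -> None:
        if self.d <= 0.0:
            raise ValueError("orifice diameter must be positive")
        if self.l <= 0.0:
            raise ValueError("throttle length must be positive")

    @property
    def Ae(self) -> float:
        """Effective flow area pi*d^2/4 (m2)."""
        return math.pi * self.d**2 / 4.0

    @classmethod
    def from_mm(cls, d_mm: float, l_mm: float) -> "ThrottleGeometry":
        return cls(d=d_mm * 1e-3, l=l_mm * 1e-3)


@dataclass(frozen=True)
class FlowState:
    """Instantaneous flow through the orifice.

    ``ni`` is +1 when air flows into the lung and -1 when it is exhausted;
    ``pu``/``pd`` are the upstream/downstream absolute pressures (pu >= pd).
    ``q`` is signed mass flow (kg/s), ``Q`` signed standard volume flow (m3/s).
    """

    q: float
    Q: float
    ni: int
    pu: float
    pd: float


@dataclass(frozen=True)
class ResistanceState:
    """Resistance bookkeeping at one instant: Re, lambda, Rr, friction drop.

    ``Rr`` and ``p_loss`` are SI (Pa s m-3, Pa); ``lam`` is NaN at zero flow
    where the friction coefficient is undefined (the resistance itself is
    pinned to the laminar limit there).
    """

    Re: float
    lam: float
    Rr: float
    p_loss: float

    @property
    def Rr_cmh2o_l_s(self) -> float:
        return self.Rr / PA_S_M3_PER_CMH2O_L_S


def critical_pressure_ratio(gas: GasProperties) -> float:
    """Choking ratio b = (2/(kappa+1))^(kappa/(kappa-1)); 0.528 for air.

    Below pd/pu = b the orifice flow is sonic and the mass flow saturates.
    """
    k = gas.kappa
    if k <= 1.0:
        raise ValueError("adiabatic index must exceed 1")
    return (2.0 / (k + 1.0)) ** (k / (k - 1.0))


def _check_pressures(pu: float, pd: float) -> None:
    if pu <= 0.0 or pd <= 0.0:
        raise ValueError("absolute pressures must be positive")
    if pd > pu:
        raise ValueError(
            "downstream pressure exceeds upstream; swap operands and flip ni"
        )


def mass_flow_exact(
    gas: GasProperties, Ae: float, pu: float, pd: float, ni: int = 1
) -> float:
    """Laval-nozzle mass flow (kg/s), subsonic branch with choked saturation.

    For pd/pu <= b the ratio is pinned at b (sonic plateau), which keeps the
    function continuous in pd/pu. Signed by the direction coefficient ``ni``.
    """
    _check_pressures(pu, pd)
    if Ae <= 0.0:
        raise ValueError("effective area must be positive")
    k = gas.kappa
    phi = max(pd / pu, critical_pressure_ratio(gas))
    bracket = phi ** (2.0 / k) - phi ** ((k + 1.0) / k)
    coeff = 2.0 * k / ((k - 1.0) * gas.R_specific * gas.T)
    return ni * Ae * pu * math.sqrt(coeff * max(bracket, 0.0))


def mass_flow_simplified(Ae: float, pu: float, pd: float, ni: int = 1) -> float:
    """Standard-state approximation q = 0.0048*ni*Ae*pu*sqrt(phi(1-phi)) (kg/s).

    Matches :func:`mass_flow_exact` within 3% over the subsonic range at
    ambient temperature; this is the law the simulator integrates.
    """
    _check_pressures(pu, pd)
    if Ae <= 0.0:
        raise ValueError("effective area must be positive")
    phi = pd / pu
    return SIMPLIFIED_FLOW_COEFF * ni * Ae * pu * math.sqrt(phi * (1.0 - phi))


def volume_flow(
    Ae: float,
    pu: float,
    pd: float,
    ni: int = 1,
    rho_std: float = 1.2,
) -> float:
    """Standard-state volume flow Q = q/rho_std (m3/s); coefficient 0.004."""
    return mass_flow_simplified(Ae, pu, pd, ni) / rho_std


def reynolds_number(q: float, d: float, mu: float) -> float:
    """Pipe Reynolds number from mass flow: Re = 4|q| / (pi d mu)."""
    if d <= 0.0 or mu <= 0.0:
        raise ValueError("diameter and viscosity must be positive")
    return 4.0 * abs(q) / (math.pi * d * mu)


def friction_coefficient(Re: float) -> float:
    """Darcy friction coefficient lambda from the piecewise Moody fit.

    Laminar 64/Re below Re=2000; linear transitional branch to Re=3000;
    linear weakly-turbulent branch above. Continuous at both junctions
    (lambda = 0.032 at Re=2000, 0.045 at Re=3000). Undefined at Re=0; the
    resistance uses the Poiseuille closed form there instead.
    """
    if Re <= 0.0:
        raise ValueError("friction coefficient undefined for Re <= 0")
    if Re < 2000.0:
        return 64.0 / Re
    if Re <= 3000.0:
        return 0.032 + (Re - 2000.0) / 1000.0 * 0.013
    return 0.045 - (Re - 3000.0) / 10000.0 * 0.015


def laminar_resistance(gas: GasProperties, geom: ThrottleGeometry) -> float:
    """Poiseuille resistance 128*mu*l/(pi*d^4) (Pa s m-3), the q -> 0 limit."""
    return 128.0 * gas.mu * geom.l / (math.pi * geom.d**4)


def resistance(gas: GasProperties, geom: ThrottleGeometry, q: float) -> float:
    """Respiratory resistance Rr = 8*lam*l*|q|/(pi^2*d^5) (Pa s m-3).

    Below Re=2000 the Moody law gives lam = 64/Re, for which Rr collapses to
    the flow-independent Poiseuille form; using that closed form removes the
    0/0 at zero flow and makes Rr continuous in q everywhere.
    """
    Re = reynolds_number(q, geom.d, gas.mu)
    if Re < 2000.0:
        return laminar_resistance(gas, geom)
    lam = friction_coefficient(Re)
    return 8.0 * lam * geom.l * abs(q) / (math.pi**2 * geom.d**5)


def pressure_loss(Rr: float, Q: float) -> float:
    """Friction pressure drop p_loss = Rr * |Q| (same pressure unit as Rr*Q)."""
    if Rr < 0.0:
        raise ValueError("resistance must be non-negative")
    return Rr * abs(Q)


def throttle_flow(
    gas: GasProperties,
    geom: ThrottleGeometry,
    p_vent_abs: float,
    p_lung_abs: float,
) -> FlowState:
    """Flow through the equivalent orifice for a ventilator/lung pressure pair.

    Upstream is whichever side is at higher pressure; ni = +1 for inspiration
    (ventilator above lung), -1 for expiration.
    """
    if p_vent_abs >= p_lung_abs:
        pu, pd, ni = p_vent_abs, p_lung_abs, 1
    else:
        pu, pd, ni = p_lung_abs, p_vent_abs, -1
    q = mass_flow_simplified(geom.Ae, pu, pd, ni)
    return FlowState(q=q, Q=q / gas.rho_std, ni=ni, pu=pu, pd=pd)


def resistance_state(
    gas: GasProperties, geom: ThrottleGeometry, flow: FlowState
) -> ResistanceState:
    """Bundle Re, lambda, Rr and the friction drop for one flow state."""
    Re = reynolds_number(flow.q, geom.d, gas.mu)
    lam = friction_coefficient(Re) if Re > 0.0 else math.nan
    Rr = resistance(gas, geom, flow.q)
    return ResistanceState(Re=Re, lam=lam, Rr=Rr, p_loss=pressure_loss(Rr, flow.Q))
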