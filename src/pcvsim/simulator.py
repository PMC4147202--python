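"""Closed-loop simulation of the ventilator - orifice - lung circuit.

Fixed-step classical Runge-Kutta (RK4) integration of the single pressure
state: at each instant the orifice mass flow is computed from the ventilator
and lung pressures (upstream is whichever is higher; ni = +1 into the lung),
and the lung pressure advances by dp/dt = RT q / (V + C p) with V affine in p
(dV = C dp). Traces carry the quantities of interest on the integration grid:
ventilator and lung pressure (cmH2O gauge), mass and standard volume flow,
Reynolds number, friction coefficient, respiratory resistance and the
ventilator-to-lung pressure difference.

Per-breath summaries and the one-at-a-time parameter sweeps (IPAP, EPAP, BPM,
Ti, Tr, C, d) with peak-pressure threshold scans live here too.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .gas_flow import (
    SIMPLIFIED_FLOW_COEFF,
    GasProperties,
    ThrottleGeometry,
    laminar_resistance,
)
from .lung import LungState
from .units import (
    M3_PER_L,
    M3_PER_ML,
    M3_PER_PA_PER_ML_CMH2O,
    M_PER_MM,
    PA_PER_CMH2O,
    PA_S_M3_PER_CMH2O_L_S,
    abs_to_gauge,
    gauge_to_abs,
)
from .ventilator import VentilatorSettings, cycle_period, pcv_pressure

__all__ = [
    "SimulationConfig",
    "SimulationTrace",
    "BreathSummary",
    "SWEEPABLE_PARAMS",
    "step",
    "simulate",
    "breath_summary",
    "sweep",
    "threshold_find",
]

#: Parameters accepted by sweep()/threshold_find(), in reported units
#: (cmH2O, min^-1, s, mL/cmH2O, mm).
SWEEPABLE_PARAMS = ("ipap", "epap", "bpm", "ti", "tr", "c", "d")

#: Flow magnitude (L/s) below which Rr is pinned to the laminar limit and
#: excluded from resistance extrema.
LOW_FLOW_CUTOFF_L_S = 1e-3


@dataclass(frozen=True)
class SimulationConfig:
    """Complete run description in SI units.

    Prefer :meth:`from_reported` to build one from clinical units
    (cmH2O, mL/cmH2O, mm, L).
    """

    settings: VentilatorSettings = field(default_factory=VentilatorSettings)
    gas: GasProperties = field(default_factory=GasProperties)
    geom: ThrottleGeometry = field(default_factory=ThrottleGeometry)
    C: float = 10.0 * M3_PER_PA_PER_ML_CMH2O  # m3/Pa
    V0: float = 1.0e-3  # m3
    dt: float = 1e-4  # s
    n_cycles: int = 4
    discard_cycles: int = 1

    def __post_init__(self) -> None:
        if self.C <= 0.0 or self.V0 <= 0.0:
            raise ValueError("compliance and initial volume must be positive")
        if self.dt <= 0.0:
            raise ValueError("step size must be positive")
        if self.dt > self.settings.tr / 20.0:
            raise ValueError(
                f"dt={self.dt} too coarse: require dt <= Tr/20 = "
                f"{self.settings.tr / 20.0}"
            )
        if not self.n_cycles > self.discard_cycles >= 1:
            raise ValueError("require n_cycles > discard_cycles >= 1")

    @classmethod
    def from_reported(
        cls,
        ipap: float = 22.0,
        epap: float = 4.0,
        bpm: float = 20.0,
        ti: float = 1.0,
        tr: float = 0.2,
        c: float = 10.0,
        d: float = 3.2,
        l: float = 10.0,
        v0: float = 1.0,
        dt: float = 1e-4,
        n_cycles: int = 4,
        discard_cycles: int = 1,
        gas: GasProperties | None = None,
    ) -> "SimulationConfig":
        """Build a config from reported units: pressures cmH2O, compliance
        mL/cmH2O, geometry mm, resting volume L."""
        return cls(
            settings=VentilatorSettings(ipap=ipap, epap=epap, bpm=bpm, ti=ti, tr=tr),
            gas=gas or GasProperties(),
            geom=ThrottleGeometry.from_mm(d, l),
            C=c * M3_PER_PA_PER_ML_CMH2O,
            V0=v0 * M3_PER_L,
            dt=dt,
            n_cycles=n_cycles,
            discard_cycles=discard_cycles,
        )

    @property
    def c_ml_cmh2o(self) -> float:
        return self.C / M3_PER_PA_PER_ML_CMH2O


@dataclass
class SimulationTrace:
    """Time series of one run, in reported units.

    t (s); p_vent, p_lung (cmH2O gauge); q (kg/s, signed, + into lung);
    Q (L/s, signed, standard state); Re; lam (NaN at zero flow);
    Rr (cmH2O/(L/s), laminar limit at low flow); p_loss (cmH2O), the
    ventilator-to-lung pressure difference |p_vent - p_lung|.
    """

    t: np.ndarray
    p_vent: np.ndarray
    p_lung: np.ndarray
    q: np.ndarray
    Q: np.ndarray
    Re: np.ndarray
    lam: np.ndarray
    Rr: np.ndarray
    p_loss: np.ndarray
    config: SimulationConfig
    converged: bool = True

    COLUMNS = ("t", "p_vent", "p_lung", "q", "Q", "Re", "lambda", "Rr", "p_loss")
    UNITS_COMMENT = (
        "# t [s], p_vent [cmH2O gauge], p_lung [cmH2O gauge], q [kg/s], "
        "Q [L/s], Re [-], lambda [-], Rr [cmH2O/(L/s)], p_loss [cmH2O]"
    )

    def __post_init__(self) -> None:
        n = len(self.t)
        for name in ("p_vent", "p_lung", "q", "Q", "Re", "lam", "Rr", "p_loss"):
            if len(getattr(self, name)) != n:
                raise ValueError("trace series must have equal length")

    def post_transient(self) -> np.ndarray:
        """Boolean mask selecting samples after the discarded cycles."""
        t0 = self.config.discard_cycles * cycle_period(self.config.settings)
        return self.t >= t0 - 1e-12

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "t": self.t,
                "p_vent": self.p_vent,
                "p_lung": self.p_lung,
                "q": self.q,
                "Q": self.Q,
                "Re": self.Re,
                "lambda": self.lam,
                "Rr": self.Rr,
                "p_loss": self.p_loss,
            }
        )

    def to_csv(self, path) -> None:
        """Write the trace as RFC-4180 CSV with a leading unit comment line."""
        with open(path, "w", newline="") as fh:
            fh.write(self.UNITS_COMMENT + "\n")
            self.to_dataframe().to_csv(fh, index=False)


@dataclass(frozen=True)
class BreathSummary:
    """Per-run extrema over post-transient cycles (reported units)."""

    p_peak: float  # cmH2O
    p_min: float  # cmH2O
    Rr_max_insp: float  # cmH2O/(L/s)
    Rr_max_exp: float  # cmH2O/(L/s)
    Rr_min: float  # cmH2O/(L/s)
    Q_peak_insp: float  # L/s
    Q_peak_exp: float  # L/s
    tidal_volume: float  # mL

    def __post_init__(self) -> None:
        if self.p_min > self.p_peak:
            raise ValueError("p_min exceeds p_peak")


def _flow_si(Ae: float, pv_abs: float, p_abs: float) -> float:
    """Signed orifice mass flow (kg/s) for ventilator/lung absolute pressures."""
    if pv_abs >= p_abs:
        pu, pd, sgn = pv_abs, p_abs, 1.0
    else:
        pu, pd, sgn = p_abs, pv_abs, -1.0
    phi = pd / pu
    return sgn * SIMPLIFIED_FLOW_COEFF * Ae * pu * math.sqrt(phi * (1.0 - phi))


def step(
    state: LungState,
    p_vent_abs: float,
    config: SimulationConfig,
    dt: float | None = None,
) -> tuple[LungState, float]:
    """Advance the lung one RK4 step under a held ventilator pressure.

    Returns the updated state and the mass flow evaluated at the step start.
    The ventilator pressure is zero-order held over the step; simulate() uses
    the identical RK4 core with stage-correct waveform values.
    """
    dt = config.dt if dt is None else dt
    if dt > config.settings.tr / 20.0:
        raise ValueError("step size violates dt <= Tr/20")
    gas, Ae, C = config.gas, config.geom.Ae, state.C
    RT = gas.R_specific * gas.T
    alpha = state.V - C * state.p  # V(p) = alpha + C p

    def f(p: float) -> float:
        return RT * _flow_si(Ae, p_vent_abs, p) / (alpha + 2.0 * C * p)

    p = state.p
    k1 = f(p)
    k2 = f(p + 0.5 * dt * k1)
    k3 = f(p + 0.5 * dt * k2)
    k4 = f(p + dt * k3)
    dp = dt / 6.0 * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
    return state.advanced(dp, gas), _flow_si(Ae, p_vent_abs, p)


def simulate(config: SimulationConfig) -> SimulationTrace:
    """Integrate the closed loop over n_cycles breaths and build the trace.

    Starts from lung pressure = EPAP (gauge) and resting volume V0; emits a
    warning and flags the trace if the peak lung pressure still changes by
    more than 0.1% between the last two cycles (periodic steady state not
    reached).
    """
    s = config.settings
    gas, geom = config.gas, config.geom
    period = cycle_period(s)
    dt = config.dt
    n_steps = int(round(config.n_cycles * period / dt))
    t = np.arange(n_steps + 1) * dt

    pv_gauge = pcv_pressure(s, t)
    pv_abs = gauge_to_abs(pv_gauge, gas.p_atm)
    pv_half = gauge_to_abs(pcv_pressure(s, t[:-1] + 0.5 * dt), gas.p_atm)

    RT = gas.R_specific * gas.T
    Ae, C = geom.Ae, config.C
    p0 = gauge_to_abs(s.epap, gas.p_atm)
    alpha = config.V0 - C * p0  # V(p) = alpha + C p

    coeff = SIMPLIFIED_FLOW_COEFF * Ae

    def f(p: float, pv: float) -> float:
        if pv >= p:
            pu, pd, sgn = pv, p, 1.0
        else:
            pu, pd, sgn = p, pv, -1.0
        phi = pd / pu
        q = sgn * coeff * pu * math.sqrt(phi * (1.0 - phi))
        return RT * q / (alpha + 2.0 * C * p)

    p_arr = np.empty(n_steps + 1)
    p_arr[0] = p0
    pv_list = pv_abs.tolist()
    pvh_list = pv_half.tolist()
    p = p0
    sixth = dt / 6.0
    half = 0.5 * dt
    for i in range(n_steps):
        pv_t, pv_h, pv_n = pv_list[i], pvh_list[i], pv_list[i + 1]
        k1 = f(p, pv_t)
        k2 = f(p + half * k1, pv_h)
        k3 = f(p + half * k2, pv_h)
        k4 = f(p + dt * k3, pv_n)
        p += sixth * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        p_arr[i + 1] = p

    # Derived channels, vectorized from the pressure series.
    pu = np.maximum(pv_abs, p_arr)
    pd_ = np.minimum(pv_abs, p_arr)
    phi = pd_ / pu
    q = np.sign(pv_abs - p_arr) * coeff * pu * np.sqrt(phi * (1.0 - phi))
    Q_l_s = q / gas.rho_std / M3_PER_L

    Re = 4.0 * np.abs(q) / (math.pi * geom.d * gas.mu)
    with np.errstate(divide="ignore"):
        lam = np.where(Re > 0.0, 64.0 / Re, np.nan)
    lam = np.where(
        (Re >= 2000.0) & (Re <= 3000.0), 0.032 + (Re - 2000.0) / 1000.0 * 0.013, lam
    )
    lam = np.where(Re > 3000.0, 0.045 - (Re - 3000.0) / 10000.0 * 0.015, lam)

    rr_lam = laminar_resistance(gas, geom)
    rr_turb = 8.0 * lam * geom.l * np.abs(q) / (math.pi**2 * geom.d**5)
    Rr_si = np.where(Re < 2000.0, rr_lam, rr_turb)

    p_lung_gauge = abs_to_gauge(p_arr, gas.p_atm)
    trace = SimulationTrace(
        t=t,
        p_vent=pv_gauge,
        p_lung=p_lung_gauge,
        q=q,
        Q=Q_l_s,
        Re=Re,
        lam=lam,
        Rr=Rr_si / PA_S_M3_PER_CMH2O_L_S,
        p_loss=np.abs(pv_gauge - p_lung_gauge),
        config=config,
    )

    steps_per_cycle = int(round(period / dt))
    peaks = [
        p_arr[k * steps_per_cycle : (k + 1) * steps_per_cycle + 1].max()
        for k in range(config.n_cycles)
    ]
    swing = gauge_to_abs(s.ipap, gas.p_atm) - gauge_to_abs(s.epap, gas.p_atm)
    if abs(peaks[-1] - peaks[-2]) > 1e-3 * swing:
        trace.converged = False
        warnings.warn(
            "periodic steady state not reached: peak pressure still drifting "
            "between the last two cycles",
            stacklevel=2,
        )
    return trace


def _cycle_phase(trace: SimulationTrace) -> np.ndarray:
    """Time within the breath cycle for every sample."""
    period = cycle_period(trace.config.settings)
    return np.mod(trace.t, period)


def breath_summary(trace: SimulationTrace) -> BreathSummary:
    """Extrema over post-transient cycles.

    Resistance extrema exclude near-zero-flow samples (|Q| below 1 mL/s)
    where Rr is pinned to the laminar limit; the overall minimum keeps them,
    which is what makes the resistance floor the laminar value.
    """
    post = trace.post_transient()
    if not post.any():
        raise ValueError("trace has no post-transient samples")
    s = trace.config.settings
    phase = _cycle_phase(trace)
    insp = post & (phase <= s.ti + 1e-12)
    exp = post & ~(phase <= s.ti + 1e-12)
    if not insp.any() or not exp.any():
        raise ValueError("empty inspiration or expiration window")
    moving = np.abs(trace.Q) >= LOW_FLOW_CUTOFF_L_S

    p_peak = float(trace.p_lung[post].max())
    p_min = float(trace.p_lung[post].min())
    dp_pa = (p_peak - p_min) * PA_PER_CMH2O
    return BreathSummary(
        p_peak=p_peak,
        p_min=p_min,
        Rr_max_insp=float(trace.Rr[insp & moving].max()),
        Rr_max_exp=float(trace.Rr[exp & moving].max()),
        Rr_min=float(trace.Rr[post].min()),
        Q_peak_insp=float(trace.Q[post].max()),
        Q_peak_exp=float(-trace.Q[post].min()),
        tidal_volume=float(trace.config.C * dp_pa / M3_PER_ML),
    )


def _apply_param(
    base: SimulationConfig, param: str, value: float
) -> SimulationConfig:
    """New config with one reported-unit parameter replaced."""
    key = param.lower()
    if key not in SWEEPABLE_PARAMS:
        raise ValueError(f"unknown sweep parameter {param!r}; use {SWEEPABLE_PARAMS}")
    if key in ("ipap", "epap", "bpm", "ti", "tr"):
        return replace(base, settings=replace(base.settings, **{key: value}))
    if key == "c":
        return replace(base, C=value * M3_PER_PA_PER_ML_CMH2O)
    return replace(base, geom=replace(base.geom, d=value * M_PER_MM))


def sweep(
    base: SimulationConfig, param: str, values
) -> list[tuple[float, BreathSummary]]:
    """One-at-a-time sensitivity: rerun the simulation for each value of one
    parameter (reported units) with everything else held at ``base``."""
    out = []
    for v in values:
        cfg = _apply_param(base, param, v)
        out.append((v, breath_summary(simulate(cfg))))
    return out


def threshold_find(
    base: SimulationConfig,
    param: str,
    values,
    reach_tol: float = 0.02,
) -> float | None:
    """Boundary value of C or d at which peak lung pressure still reaches IPAP.

    A run "reaches IPAP" when p_peak >= IPAP * (1 - reach_tol); equality
    counts. Reaching improves as C decreases and as d increases, so the
    threshold is the largest passing C, respectively the smallest passing d.
    Returns None when no scanned value reaches IPAP.
    """
    values = list(values)
    if not values:
        raise ValueError("empty scan")
    results = sweep(base, param, sorted(values))
    passing = []
    for v, summary in results:
        ipap = v if param.lower() == "ipap" else base.settings.ipap
        if summary.p_peak >= ipap * (1.0 - reach_tol):
            passing.append(v)
    if not passing:
        return None
    return min(passing) if param.lower() == "d" else max(passing)
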