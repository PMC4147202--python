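"""Unit conversion constants and helpers.

Internally everything is SI (Pa absolute, m3, kg/s, m). The API surface and all
CSV output use the units clinicians read: cmH2O gauge pressure, L/s volume
flow, mL/cmH2O compliance, mm geometry. Conversions are exposed as named
constants so downstream output is bit-stable.
"""

from __future__ import annotations

#: Pascal per centimetre of water column.
PA_PER_CMH2O = 98.0665

#: Reference atmospheric pressure (Pa, absolute).
P_ATM = 101325.0

#: m3/Pa per mL/cmH2O (compliance conversion): 1e-6 / 98.0665.
M3_PER_PA_PER_ML_CMH2O = 1e-6 / PA_PER_CMH2O

#: Pa.s/m3 per cmH2O/(L/s) (resistance conversion): 98.0665 / 1e-3.
PA_S_M3_PER_CMH2O_L_S = PA_PER_CMH2O / 1e-3

#: m3 per litre / per millilitre.
M3_PER_L = 1e-3
M3_PER_ML = 1e-6

#: metre per millimetre.
M_PER_MM = 1e-3


def cmh2o_to_pa(p_cmh2o):
    """Gauge cmH2O -> gauge Pa."""
    return p_cmh2o * PA_PER_CMH2O


def pa_to_cmh2o(p_pa):
    """Gauge Pa -> gauge cmH2O."""
    return p_pa / PA_PER_CMH2O


def gauge_to_abs(p_cmh2o, p_atm: float = P_ATM):
    """Gauge pressure in cmH2O -> absolute pressure in Pa."""
    return p_atm + p_cmh2o * PA_PER_CMH2O


def abs_to_gauge(p_pa, p_atm: float = P_ATM):
    """Absolute pressure in Pa -> gauge pressure in cmH2O."""
    return (p_pa - p_atm) / PA_PER_CMH2O
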