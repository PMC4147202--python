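# Model and methods

## The system

`pcvsim` models a pressure-controlled ventilation (PCV) bench: a ventilator
driving a passive test lung through a tube and airway. Because ventilation
pressures are tiny compared with atmosphere (a few tens of cmH2O), the tube
and airway store negligible gas and the whole circuit collapses to a pure
pneumatic network — a pressure source, a single equivalent orifice (diameter
`d`, length `l`) that lumps all flow resistance, and one variable-volume
container of compliance `C = dV/dp` for the lung. The test lung that this
emulates has a 3.2 mm inlet, which dominates the circuit resistance, so the
tube's own contribution is neglected.

Assumptions: ideal gas; uniform state within the container; isothermal at
ambient temperature; no leakage; quasi-steady one-dimensional orifice flow.

## Governing equations

**Orifice flow.** Mass flow through the equivalent orifice follows the
converging-nozzle (Laval) law. Flow chokes when the downstream/upstream
pressure ratio falls below `b = (2/(kappa+1))^(kappa/(kappa-1))` (0.528 for
air); PCV never gets near that, so the operating branch is subsonic. At
ambient temperature the subsonic law is well approximated by the
standard-state form

    q = 0.0048 * ni * Ae * pu * sqrt(phi (1 - phi)),   phi = pd/pu,

with `q` in kg/s, effective area `Ae = pi d^2/4` in m2, absolute pressures in
Pa, and `ni = +1` into the lung, `-1` out. The coefficient 0.0048 is adopted
as a fixed constant; the package verifies it stays within 3% of the exact
nozzle law over `phi` in [0.528, 0.995] at 293 K. Standard volume flow is
`Q = q / rho_std` with `rho_std = 1.2 kg/m3` (equivalently a 0.004
coefficient). The exact law, including the choked plateau, is implemented
alongside for verification.

**Lung pressure.** Isothermal mass balance of the container (`pV = mRT`,
`dV = C dp`) gives

    dp/dt = R T q V / (V^2 + C m R T) = R T q / (V + C p),

so the lung state reduces to one pressure, with volume affine in pressure.
In the compliance-dominated limit `C p >> V` and at the standard density this
collapses to the familiar `dp/dt = Q / C`.

**Resistance.** Respiratory resistance is the Darcy friction drop of the
orifice, `Rr = 8 lam l q / (pi^2 d^5)`, with the friction coefficient from a
three-branch piecewise fit of the Moody chart: `64/Re` below Re = 2000,
`0.032 + (Re-2000)/1000 * 0.013` to Re = 3000, and
`0.045 - (Re-3000)/10000 * 0.015` above, continuous at both junctions, with
`Re = 4|q| / (pi d mu)`. In the laminar branch `Rr` reduces algebraically to
the Poiseuille resistance `128 mu l / (pi d^4)`, which is used directly for
Re < 2000 — this removes the 0/0 at zero flow and is why the resistance
"floor" at flow reversals is flow-independent. Note the turbulent branch is a
local linear fit: it would go non-positive beyond Re ≈ 3.3e4, far above
anything this system reaches (Re peaks near 1.3e4 at the baseline operating
point). Relative roughness is absorbed into the fit, not a free parameter.

Two pressure-loss notions coexist and are deliberately kept distinct. The
*friction drop* `Rr * |Q|` (exposed by `gas_flow.pressure_loss`) is the
Darcy-model drop consistent with `Rr`. The *ventilator-to-lung difference*
`|p_vent - p_lung|` is what the trace's `p_loss` column records, because that
is the definitional pressure loss of the circuit and the quantity whose
dynamics the parameter studies discuss. Under the orifice-flow law the two
are not numerically equal — the orifice sustains most of the drop through
inertial/contraction losses the Darcy wall-friction term does not represent —
and conflating them would make the trace internally inconsistent.

## Parameters, units, defaults

| Parameter | Unit (API) | Default | Notes |
|---|---|---|---|
| IPAP / EPAP | cmH2O gauge | 22 / 4 | plateau pressures of the trapezoid |
| BPM | min^-1 | 20 | sets only the period 60/BPM |
| Ti / Tr | s | 1.0 / 0.2 | inspiratory time, pressure rise time |
| C | mL/cmH2O | 10 | constant within a run |
| d | mm | 3.2 | equivalent orifice diameter |
| l | mm | 10 | throttle length (see below) |
| V0 | L | 1.0 | resting lung volume at EPAP |
| dt | s | 1e-4 | fixed RK4 step; must satisfy dt <= Tr/20 |
| cycles | — | 4 (discard 1) | transient handling |

Gas constants: kappa = 1.4, R = 287 J/(kg K), T = 293.15 K, mu = 1.82e-5
Pa s, rho_std = 1.2 kg/m3, p_atm = 101325 Pa. Conversions are fixed
constants: 1 cmH2O = 98.0665 Pa, 1 mL/cmH2O = 1.0197e-8 m3/Pa,
1 cmH2O/(L/s) = 9.80665e4 Pa s/m3.

The throttle length `l` is not independently measurable for a lumped
orifice; the 10 mm default is calibrated so that the laminar-limit
resistance at d = 3.2 mm equals the observed resistance floor of
0.72 cmH2O/(L/s). It is an ordinary config parameter and `Rr` scales
linearly with it.

The ventilator waveform is the ideal PCV trapezoid with a *symmetric* fall:
the expiratory drop takes the same time Tr as the rise, since the rise time
also shapes flow at the start of expiration. Each cycle starts at the
beginning of the inspiratory rise; inspiration is [0, Ti], expiration
(Ti, period]. The plateau ends exactly at Ti.

## Numerics

Fixed-step classical RK4 on the single pressure state, default dt = 1e-4 s,
with the waveform evaluated at stage times (the public single-`step` API
holds the ventilator pressure over the step instead, since it receives one
pressure value). A fixed step keeps traces bit-stable across runs and
platforms; halving dt moves every reported summary statistic by under 0.2%,
and the loop agrees with an adaptive high-accuracy integrator to within
0.01 cmH2O. Simulations start from lung pressure = EPAP and run 4 cycles,
discarding the first as transient; if the peak pressure still drifts by more
than 0.1% of the swing between the last two cycles the trace is flagged
non-converged and a warning is emitted. Flow direction at p_vent = p_lung is
an exact zero (no tie-break needed); resistance extrema in breath summaries
exclude samples with |Q| < 1 mL/s, where Rr sits pinned at the laminar
floor, and the reported minimum resistance is exactly that floor.

Because the flow law goes as sqrt(delta p), the lung closes the last part of
the pressure gap in finite time rather than exponentially — this is what
makes "reaching IPAP" a sharp threshold in C and d rather than an
asymptotic statement. A run "reaches IPAP" when its peak lung pressure is
within 2% of IPAP (boundary equality counts).

## Compliance estimation

Integrating the mass balance over one inspiration gives exactly

    rho_std * R * T * int(Q dt) = delta_p * (V_start + C * p_end),

so the estimator inverts this:
`C = (rho_std R T int(Q dt) / delta_p - V_start) / p_end`, averaged over
post-transient cycles. The familiar tidal-volume-over-pressure-swing ratio
`int(Q dt)/delta_p` is the limit of this expression for a vanishing resting
volume at standard density; at V_start = 1 L it overestimates C by roughly
10% because part of the inhaled gas compresses the resident gas instead of
expanding the lung (and standard volume flow differs from local volume flow
by the density ratio). V_start cannot be identified from mouth flow and
pressure alone over a small pressure swing — the regression surface is
degenerate — so it is an input with the simulator's resting-volume default.
Windows with a pressure swing below 0.5 cmH2O are rejected as degenerate.
Recovery on clean simulated traces is exact to rounding; with 0.2 cmH2O of
sensor noise it stays within a few percent.

The choice V0 = 1 L itself barely matters for the dynamics: the effective
capacitance is V + C p ≈ 11 L worth of equivalent volume, so doubling V0
shifts summary pressures by well under 1% of the swing (tested).

## Synthetic recordings

`generate_recording` overlays seeded Gaussian noise (defaults: 0.2 cmH2O on
pressure, 0.02 L/s on flow) on the clean simulated lung pressure and flow,
emulating raw bench sensor traces; a centered moving-average smoother stands
in for heavier signal-processing pipelines. What these fixtures do *not*
emulate: pressure-dependent (nonlinear) compliance, circuit leakage, sensor
drift, or the real ventilator's imperfect pressure waveform. Tests passing
on these fixtures therefore validate the model and the estimators under the
model's own assumptions, not against bench hardware; measured traces from a
real ventilator (whose delivered waveform deviates from the ideal trapezoid)
will differ quantitatively, which is also why the simulated resistance
extrema are compared with bench values only to within 15%.

## Known limitations

- Single compartment, single lumped orifice: no airway network, no separate
  exhalation-valve path (expiration is reverse flow through the same
  orifice toward the waveform-held ventilator pressure), no inertance.
- Constant compliance within a run; real test lungs stiffen with pressure.
- Isothermal only; no heat-transfer model.
- The Moody fit is local to Re ≲ 3e4; do not push the geometry/pressures
  far outside the ventilation regime.
- The ideal trapezoid stands in for the real ventilator's output, so
  experimental waveform artefacts (overshoot, rounded corners, reported
  average IPAP/EPAP offsets) are out of scope.
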