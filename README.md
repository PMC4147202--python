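# pcvsim

Simulation of pressure-controlled ventilation (PCV) of a passive test lung,
for people studying respiratory mechanics, ventilator settings, or bench
lung simulators. The ventilation circuit is treated as a pure pneumatic
system: the ventilator is a pressure source driving the ideal PCV trapezoid
(EPAP → IPAP rise over the rise time T_r, plateau to the inspiratory time
T_i, symmetric fall, expiratory hold), the tube and airway lump into a
single equivalent orifice (diameter d, length l), and the lung is an
isothermal variable-volume container of compliance C = dV/dp.

The model couples three relations:

- subsonic orifice mass flow (standard-state nozzle law),
  `q = 0.0048 · n_i · A_e · p_u · sqrt(φ(1−φ))` with `φ = p_d/p_u`,
  `A_e = πd²/4`, choking ratio `b = (2/(κ+1))^(κ/(κ−1)) ≈ 0.528` never
  reached in the PCV pressure range;
- isothermal lung pressure dynamics,
  `dp/dt = RTqV/(V² + CmRT) = RTq/(V + Cp)` with `dV = C dp`;
- Reynolds-dependent respiratory resistance from a piecewise Moody fit,
  `R_r = 8λlq/(π²d⁵)`, `λ = 64/Re` laminar (where R_r reduces to the
  Poiseuille form `128μl/(πd⁴)`), linear transitional and turbulent branches
  above, with `Re = 4|q|/(πdμ)`.

On top of the integrator the package provides per-breath summaries (peak and
minimum lung pressure, inspiratory/expiratory resistance extrema, flow peaks,
tidal volume), compliance estimation from pressure/flow traces, seeded
synthetic "bench recordings" with sensor noise, one-at-a-time parameter
sweeps over IPAP, EPAP, BPM, T_i, T_r, C and d, and threshold scans for the
largest compliance / smallest orifice diameter at which the lung still
reaches IPAP. See `docs/methods.md` for the model details and limitations.

## Worked example

Simulate the default operating point — IPAP 22 / EPAP 4 cmH2O, 20
breaths/min, T_i 1 s, T_r 0.2 s, C 10 mL/cmH2O, d 3.2 mm, l 10 mm — and scan
the two threshold parameters:

```
$ pcvsim simulate --out trace.csv
wrote trace.csv: p_peak=22.00 cmH2O, Rr 0.72-3.84 cmH2O/(L/s), tidal volume 180 mL
$ pcvsim threshold --param c --values 5,10,15
10
$ pcvsim threshold --param d --values 2.4,3.2,4.0
3.2
```

Reading the numbers: the lung pressure reaches the 22 cmH2O IPAP plateau
(the lag behind the ventilator is visible in the trace), the respiratory
resistance fluctuates between its laminar floor of 0.72 cmH2O/(L/s) at flow
reversals and ≈3.8 cmH2O/(L/s) at peak flow, and the 18 cmH2O pressure swing
through a 10 mL/cmH2O compliance moves a 180 mL tidal volume. The threshold
scans show IPAP is reached for compliances up to 10 mL/cmH2O and orifice
diameters down to 3.2 mm; beyond those the peak pressure falls short. The
trace CSV carries nine columns (`t, p_vent, p_lung, q, Q, Re, lambda, Rr,
p_loss`) with a unit comment line.

The same from Python:

```python
import pcvsim as p

config = p.SimulationConfig.from_reported(c=10.0, d=3.2)
trace = p.simulate(config)
summary = p.breath_summary(trace)          # peaks, resistance range, tidal volume
c_hat = p.estimate_compliance(trace)       # -> 10.00 mL/cmH2O
```

Other subcommands: `pcvsim sweep --param ipap --values 18,22,24` (one summary
row per value), `pcvsim fixtures --seed 7` (noisy synthetic recording), and
`pcvsim estimate-c --input recording.csv --smooth-window 5`. Every flag can
also come from a flat YAML config via `--config`.

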