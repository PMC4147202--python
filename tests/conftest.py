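"""Shared fixtures: expensive simulations run once per session."""

import pytest
from hypothesis import settings

import pcvsim as p

settings.register_profile("ci", derandomize=True, max_examples=50)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def gas():
    return p.GasProperties()


@pytest.fixture(scope="session")
def geom():
    return p.ThrottleGeometry.from_mm(3.2, 10.0)


@pytest.fixture(scope="session")
def baseline_config():
    """Prototype operating point: IPAP 22 / EPAP 4 / 20 bpm / Ti 1 s / Tr 0.2 s,
    C = 10 mL/cmH2O, d = 3.2 mm, l = 10 mm, 4 cycles RK4 at dt = 1e-4 s."""
    return p.SimulationConfig.from_reported()


@pytest.fixture(scope="session")
def baseline_trace(baseline_config):
    return p.simulate(baseline_config)


@pytest.fixture(scope="session")
def baseline_summary(baseline_trace):
    return p.breath_summary(baseline_trace)


@pytest.fixture(scope="session")
def compliance_sweep(baseline_config):
    """Traces for C in {5, 10, 15} mL/cmH2O, reused across recovery and
    threshold tests."""
    traces = {}
    for c in (5.0, 10.0, 15.0):
        cfg = p.SimulationConfig.from_reported(c=c)
        traces[c] = p.simulate(cfg)
    return traces


@pytest.fixture(scope="session")
def diameter_sweep(baseline_config):
    return p.sweep(baseline_config, "d", [2.4, 3.2, 4.0])


@pytest.fixture(scope="session")
def half_dt_summary(baseline_config):
    import dataclasses

    cfg = dataclasses.replace(baseline_config, dt=baseline_config.dt / 2.0)
    return p.breath_summary(p.simulate(cfg))


@pytest.fixture(scope="session")
def noisy_recording(baseline_config):
    """Seeded synthetic recording with 0.2 cmH2O pressure noise."""
    return p.generate_recording(
        baseline_config, noise_sd_p=0.2, noise_sd_Q=0.02, seed=1234
    )
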