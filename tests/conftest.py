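"""Shared fixtures: calibrated volume model, default protocol, and the
(expensive) pump-leak calibration and scenario battery, built once."""

from __future__ import annotations

import numpy as np
import pytest

import dexsim as dx


@pytest.fixture(scope="session")
def volume_params() -> dx.VolumeModelParams:
    """Volume model calibrated at normal media, V = -48 mV, fo_init = 0.3."""
    return dx.VolumeModelParams.calibrated()


@pytest.fixture(scope="session")
def protocol() -> dx.DEXSYProtocol:
    return dx.DEXSYProtocol.default()


@pytest.fixture(scope="session")
def fo_normal(volume_params) -> float:
    return dx.solve_fo(volume_params, 0.0, -48.0).fo


@pytest.fixture(scope="session")
def fo_depolarized(volume_params) -> float:
    return dx.solve_fo(volume_params, 0.0, -10.0).fo


def simulate_3xm(fa: float, protocol: dx.DEXSYProtocol, **kw):
    """Noiseless three-site signal table at ECS fraction ``fa``."""
    system = dx.CompartmentSystem.three_site(fa, **kw)
    return dx.simulate_dexsy(system, dx.ExchangeSpec.three_site(300.0, 30.0),
                             protocol)


@pytest.fixture(scope="session")
def plm_setup():
    """Initial state, parameters with x_i, and the calibrated pump rate."""
    params = dx.PLMParameters()
    initial, params = dx.default_initial_state(params)
    rate = dx.calibrate_pump_rate(params)
    return initial, params, rate


@pytest.fixture(scope="session")
def fig4_table(plm_setup):
    initial, params, rate = plm_setup
    return dx.run_fig4_scenarios(params, pump_rate=rate)
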