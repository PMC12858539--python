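import numpy as np
import pytest

from coroshear import (
    HemoConfig,
    StenosisSpec,
    make_flow_waveform,
    make_stenotic_vessel,
    solve_reduced_order,
)

# reference conditions of the analytic Poiseuille benchmark
MU = 3.5e-3  # Pa s
Q = 1.0e-6  # m^3/s
R = 2.0e-3  # m
TAU_POISEUILLE = 4.0 * MU * Q / (np.pi * R**3)  # 0.557 Pa


@pytest.fixture(scope="session")
def uniform_tube():
    return make_stenotic_vessel(StenosisSpec(severity=0.0), 100, 16)


@pytest.fixture(scope="session")
def stenotic_tube():
    return make_stenotic_vessel(StenosisSpec(severity=0.5), 120, 16)


@pytest.fixture(scope="session")
def steady_waveform():
    return make_flow_waveform(period=0.8, mean_flow=Q, pulsatility_amplitude=0.0)


@pytest.fixture(scope="session")
def pulsatile_waveform():
    return make_flow_waveform(period=0.8, mean_flow=Q, pulsatility_amplitude=0.5)


@pytest.fixture(scope="session")
def hemo_config():
    return HemoConfig(viscosity=MU)


@pytest.fixture(scope="session")
def steady_wall(uniform_tube, steady_waveform, hemo_config):
    wall, _ = solve_reduced_order(uniform_tube, steady_waveform, hemo_config)
    return wall
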