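"""Shared fixtures: system constants and the four worked-example VA triples.

The heavy objects (simulated exemplar trajectories) are session-scoped so the
ramp protocol runs once per exemplar for the whole suite.
"""

import pytest

from motopic import (
    ActiveParameters,
    DetectionConfig,
    RampProtocol,
    SystemProperties,
    VAFactors,
    classify_trajectory,
    invert_cable_parameters,
    simulate_ramp,
)

# Published worked examples: VA triple -> (cable 5-tuple, firing type label).
EXEMPLARS = {
    "I": ((0.97, 0.63, 0.84), (4.805, 0.051, 1.375, 49.499, 0.626)),
    "III": ((0.65, 0.003, 0.08), (5.045, 0.002, 0.003, 52.425, 0.024)),
    "IV_partial": ((0.96, 0.57, 0.81), (4.796, 0.054, 1.068, 49.952, 0.542)),
    "IV_full": ((0.94, 0.38, 0.69), (4.871, 0.039, 0.502, 50.772, 0.378)),
}


@pytest.fixture(scope="session")
def sysp():
    return SystemProperties()


@pytest.fixture(scope="session")
def active():
    return ActiveParameters()


@pytest.fixture(scope="session")
def ramp():
    return RampProtocol()


@pytest.fixture(scope="session")
def detection():
    return DetectionConfig()


@pytest.fixture(scope="session")
def exemplar_runs(sysp, active, ramp, detection):
    """Simulate and classify the four worked examples once per session."""
    runs = {}
    for label, (va, _) in EXEMPLARS.items():
        cable = invert_cable_parameters(sysp, VAFactors(*va))
        traj = simulate_ramp(cable, sysp, active, ramp)
        ci = classify_trajectory(traj, ramp, detection)
        runs[label] = (cable, traj, ci)
    return runs
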