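import numpy as np
import pytest

from gapdyn.circuit import GeneCircuit, StageSchedule, simulate_row
from gapdyn.synth import (C13_POSITIONS, generate_ground_truth_circuit,
                          generate_synthetic_gradients)


@pytest.fixture(scope="session")
def schedule():
    return StageSchedule()


@pytest.fixture(scope="session")
def c14a():
    return StageSchedule.c14a_only()


@pytest.fixture(scope="session")
def gradients():
    return generate_synthetic_gradients(seed=1)


@pytest.fixture(scope="session")
def full_circuit():
    return generate_ground_truth_circuit("full", seed=1)


@pytest.fixture(scope="session")
def acdc_circuit():
    return generate_ground_truth_circuit("acdc", seed=1)


@pytest.fixture(scope="session")
def t1_states(full_circuit, gradients, schedule):
    """Full-model daughter positions and states at C14A onset (zero C13
    initials), shared across tests that analyse C14A only."""
    t1 = schedule.c14a_start
    trajs = simulate_row(full_circuit, gradients, C13_POSITIONS,
                         np.zeros((C13_POSITIONS.size, 4)), schedule, [t1])
    positions = np.array([tr.position for tr in trajs])
    states = np.stack([tr.states[-1] for tr in trajs])
    return positions, states


def autonomous_circuit(seed, n=3, repressive=True):
    """Seeded random circuit without maternal inputs, used for frozen-field
    and census tests; the repressive ensemble mixes mono- and multistable
    cases."""
    rng = np.random.default_rng(seed)
    if repressive:
        W = rng.uniform(-0.08, 0.0, (n, n))
        W[np.diag_indices(n)] = rng.uniform(0.0, 0.01, n)
        h = rng.uniform(0.0, 3.0, n)
    else:
        W = rng.uniform(-0.05, 0.02, (n, n))
        h = rng.uniform(-4.0, 2.0, n)
    return GeneCircuit(tuple("abcdefg"[:n]), (), rng.uniform(12, 18, n),
                       rng.uniform(0.08, 0.12, n), W, np.zeros((0, n)), h,
                       name=f"random-{seed}")
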