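import numpy as np
import pytest

from posturolab import (
    BalanceModelParams,
    TernaryDesign,
    build_learning_sequence,
    build_prts,
    simulate_sway,
)


@pytest.fixture(scope="session")
def design():
    return TernaryDesign()


@pytest.fixture(scope="session")
def pp4_stimulus(design):
    """Four-cycle pp4 PRTS at 100 Hz (first cycle discarded downstream)."""
    return build_prts(design, 1.78, 4)


@pytest.fixture(scope="session")
def learning_stimulus():
    return build_learning_sequence()


@pytest.fixture(scope="session")
def quiet_params():
    """Noise-free default subject."""
    return BalanceModelParams()


@pytest.fixture(scope="session")
def pp4_recording(pp4_stimulus, quiet_params):
    """Noise-free simulated pp4 trial (shared across spectral tests)."""
    return simulate_sway(pp4_stimulus, quiet_params, seed=0)


def gaussian_cycle_pool(n_cycles, rng, cycle_len=8, scale=1.0):
    """Toy CycleSet whose response rows are i.i.d. Gaussian."""
    from posturolab import CycleSet

    return CycleSet(
        stimulus_cycles=np.zeros((n_cycles, cycle_len)),
        response_cycles=rng.normal(0.0, scale, (n_cycles, cycle_len)),
        cycle_duration=float(cycle_len),
        sample_rate=1.0,
    )
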