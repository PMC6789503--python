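import numpy as np
import pytest

from lucnorm import ReplicateSet, SimulationConfig, simulate_experiment


@pytest.fixture
def outlier_fixture() -> ReplicateSet:
    """Nine points exactly on F = 3R plus one gross outlier at (1, 100)."""
    ren = np.append(np.arange(1.0, 10.0), 1.0)
    fir = np.append(3.0 * np.arange(1.0, 10.0), 100.0)
    return ReplicateSet(renilla=ren, firefly=fir)


@pytest.fixture
def clean_experiment():
    """Factory for clean (outlier-free) simulated experiments."""

    def make(seed: int, **overrides) -> ReplicateSet:
        defaults = dict(
            true_activity=10.0, n=10, alpha=6.0, beta=2.0,
            sigma11=1.0, sigma12=1.0, seed=seed,
        )
        defaults.update(overrides)
        return simulate_experiment(SimulationConfig(**defaults)).data

    return make
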