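import numpy as np
import pytest

from wahr import SimConfig, TrialDataset, WeightScheme


@pytest.fixture
def toy_dataset() -> TrialDataset:
    """Four subjects, one per group pattern: I has an event of type 1 at t=2
    and a censoring at 3; C has an event of type 2 at t=1 and a censoring
    at 3."""
    return TrialDataset(
        times=[2.0, 3.0, 1.0, 3.0],
        causes=[1, 0, 2, 0],
        groups=["I", "I", "C", "C"],
        k=2,
        tau=3.0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.Generator(np.random.MT19937(20240917))


@pytest.fixture
def simulated_dataset():
    """A mid-sized continuous-time dataset from the first preset scenario."""
    from wahr import simulate_trial

    cfg = SimConfig(
        "scenario_1", tau=1.0, weights=WeightScheme((1.0, 0.1)), n_per_group=60,
        reps=1, n_perm=0, seed=7,
    )
    return cfg, simulate_trial(cfg)
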