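import pytest

from frfit import SimConfig, simulate_study_design, simulate_trials

EXT = (2, 4, 8, 16, 32, 64, 128, 256)


@pytest.fixture(scope="session")
def typeii_trials():
    """Clean Type-II dataset: binomial noise matching the fit likelihood."""
    cfg = SimConfig(attack_rate=1.5, handling_time=0.08, densities=EXT,
                    replicates=25, seed=11)
    return simulate_trials(cfg)


@pytest.fixture(scope="session")
def small_group():
    """A modest single-group dataset (base ladder, 10 reps)."""
    cfg = SimConfig(attack_rate=1.0, handling_time=0.1, replicates=10, seed=5)
    return simulate_trials(cfg)


@pytest.fixture(scope="session")
def study_dataset():
    """Full factorial synthetic dataset (both experiments, mixed prey)."""
    return simulate_study_design(seed=1)
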