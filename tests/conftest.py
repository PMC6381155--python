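import pytest

from sawpi import sawcount


@pytest.fixture(scope="session")
def exact_tables():
    """Exact configuration counts for N_S = 0..10 (shared: ~20 s to build)."""
    return sawcount.enumerate_exact(10)


@pytest.fixture(scope="session")
def mc_series_12():
    """Monte-Carlo omega estimates for N_S = 1..12 from one 1e5-trial batch."""
    return sawcount.simulate_omega_series(max_step=12, n_trials=100_000, rng_seed=20260920)
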