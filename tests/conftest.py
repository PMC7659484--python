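import pytest

import cytofuzz as cf


@pytest.fixture(scope="session")
def design():
    return cf.make_design_table()


@pytest.fixture(scope="session")
def default_config():
    return cf.SimulationConfig()


@pytest.fixture(scope="session")
def noiseless_config():
    """Noise model switched off: ideal counter, no well CV, no batch effect."""
    return cf.SimulationConfig(
        counting_volume_ml=None, well_cv=0.0, batch_sd=0.0, n_datasets=1,
        wells_per_condition=1, seed=0,
    )


@pytest.fixture(scope="session")
def sim_counts(design):
    """One default-noise simulated plate, shared across read-only tests."""
    return cf.simulate_trajectories(design, cf.SimulationConfig(seed=1234))


@pytest.fixture(scope="session")
def rate_table(sim_counts, design):
    return cf.normalize_rates(cf.compute_growth_table(sim_counts, design))

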