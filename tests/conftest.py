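"""Shared fixtures: a small fast world and the full default world."""

import numpy as np
import pytest

import tradeair as ta


@pytest.fixture(scope="session")
def small_config():
    return ta.WorldConfig(
        n_domestic=4, n_foreign=2, n_sectors=2, grid_shape=(20, 20),
        n_draws=50, seed=11,
    )


@pytest.fixture(scope="session")
def small_world(small_config):
    return ta.generate_world(small_config)


@pytest.fixture(scope="session")
def default_world():
    """The standard study conditions: 6 provinces, 3 foreign regions,
    3 sectors, 60x60 grid, 1000 IER draws."""
    return ta.generate_world(ta.WorldConfig(seed=20))


@pytest.fixture(scope="session")
def default_accounts(default_world):
    w = default_world
    coeff = ta.technical_coefficients(w.economy)
    tensor = ta.embodied_emissions(w.intensities, coeff, w.economy, w.pollutants)
    return tensor, ta.accounts(tensor)


@pytest.fixture(scope="session")
def default_fields(default_world, default_accounts):
    """Per-scenario (C_TRE, C_noTRE) pairs on the default world."""
    w = default_world
    tensor, acc = default_accounts
    specs = {s.scenario_id: s
             for s in ta.default_scenarios(w.economy.regions[w.config.n_domestic:])}
    scen = {sid: ta.build_scenario(tensor, acc, spec) for sid, spec in specs.items()}
    baseline = ta.disperse(scen[1].values, w.kernels)
    fields = {}
    for sid, s in scen.items():
        model = ta.disperse(s.values, w.kernels)
        A = ta.change_ratio(baseline, model)
        fields[sid] = ta.decompose_exposure(w.satellite, A)
    return scen, fields


def make_autarkic_table(n_regions: int, n_domestic: int, seed: int = 0):
    """A balanced economy with no inter-regional flows at all (1 sector)."""
    rng = np.random.default_rng(seed)
    R = n_regions
    Z = np.diag(rng.uniform(5.0, 15.0, R))
    Y = np.diag(rng.uniform(20.0, 40.0, R))
    x = Z.sum(1) + Y.sum(1)
    return ta.LinkedMRIOTable(
        regions=[f"r{i}" for i in range(R)], n_domestic=n_domestic,
        sectors=["s"], Z=Z, Y=Y, x=x,
    )
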