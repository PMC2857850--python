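import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import geoblup as gb

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def small_sim():
    """A small cross population with phenotypes: shared across tests."""
    cfg = gb.SimConfig(
        seed=11,
        n_fathers=2,
        n_mothers=3,
        offspring_per_cross=20,
        n_markers=60,
        n_qtl=10,
        phenotyped_fraction=0.6,
    )
    return cfg, gb.simulate_population(cfg)


@pytest.fixture(scope="session")
def small_stage1(small_sim):
    cfg, sim = small_sim
    s1 = gb.run_stage1(gb.series_from_long(sim.phenotypes), cfg.target_time)
    return s1


def random_genotype_matrix(rng, n, m):
    Z = rng.integers(-1, 2, size=(n, m)).astype(float)
    return gb.GenotypeMatrix(
        Z, tuple(f"i{k}" for k in range(n)), tuple(f"m{k}" for k in range(m))
    )
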