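import dataclasses

import numpy as np
import pytest

from neuromuscle import inverse as inv
from neuromuscle import io as nio


@pytest.fixture(scope="session")
def fr_cell():
    return nio.load_preset("MN", "FR")


@pytest.fixture(scope="session")
def s_cell():
    return nio.load_preset("MN", "S")


@pytest.fixture(scope="session")
def sol_fiber():
    return nio.load_preset("MT", "SOL")


@pytest.fixture(scope="session")
def mg_fiber():
    return nio.load_preset("MT", "MG")


@pytest.fixture(scope="session")
def small_mu_pool():
    """4-cell motor-unit pool spanning the CI range (coarse lookup grid
    keeps construction fast; live refinement restores accuracy)."""
    ci = inv.ci_rank_distribution(4, 1.4, 3.0, gamma=1.0)
    return inv.build_population(inv.PopulationSpec("MU", ci,
                                                   lookup_n_grid=7))


@pytest.fixture(scope="session")
def passive_mu_pool(small_mu_pool):
    """The same pool with dendritic PIC channels removed."""
    cells = [dataclasses.replace(
        c, mn_rmp=dataclasses.replace(c.mn_rmp, g_cal_d=0.0))
        for c in small_mu_pool.cells]
    return dataclasses.replace(small_mu_pool, cells=cells)
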