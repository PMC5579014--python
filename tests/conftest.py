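import numpy as np
import pytest

from seapan import IslandModelSpec, simulate_genotypes
from seapan.pipeline import RunConfig, run_dispersal_chain, two_gyre_domain, two_gyre_field


@pytest.fixture(scope="session")
def two_gyre_chain():
    """Full dispersal chain on the planted two-gyre barrier domain.

    The central break sits between coastal cells 27 and 28; the western
    shore is cells 0..27, the eastern shore 28..55.
    """
    grid = two_gyre_domain()
    fld = two_gyre_field(grid, years=2, seed=1)
    cfg = RunConfig.demo(seed=1)
    trajset, C, S, graph, partition, barriers = run_dispersal_chain(
        grid, fld, cfg)
    return {
        "grid": grid, "field": fld, "config": cfg, "trajset": trajset,
        "C": C, "S": S, "graph": graph, "partition": partition,
        "barriers": barriers, "break_cell": grid.n_coastal // 2,
    }


@pytest.fixture(scope="session")
def panmictic_data():
    """One island-model draw at the high-migration (panmictic) limit."""
    spec = IslandModelSpec(migration_rate=0.5)
    return simulate_genotypes(spec, seed=11)


@pytest.fixture(scope="session")
def structured_data():
    """Two long-isolated demes (fixed differences limit)."""
    spec = IslandModelSpec(migration_rate=0.0, n_demes=2, deme_size=50,
                           n_generations=1000, sample_sizes=20)
    return simulate_genotypes(spec, seed=2)


def side_of(cells, break_cell):
    """True shore side (0 = west, 1 = east) of coastal cell ids."""
    return (np.asarray(cells) >= break_cell).astype(int)
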