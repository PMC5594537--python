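import numpy as np
import pytest

from oryzamir.config import RunConfig
from oryzamir.simulate import SimulationConfig, queries_from_simulation, simulate

#: compact 3-taxon tree for fast structural tests (branch lengths in MY)
SMALL_TREE = "((A_taxon:1.0,B_taxon:1.0):5.0,C_taxon:6.0);"


@pytest.fixture(scope="session")
def small_cohort():
    """A small planted cohort: 4 families + the cluster family, 10 taxa."""
    cfg = SimulationConfig(n_families=4, genome_len=90000, seed=11)
    genomes, features, te_lib, osets, truth = simulate(cfg)
    queries = queries_from_simulation(osets, cfg.query_species, cluster_spec=cfg.cluster_spec)
    return {
        "cfg": cfg,
        "genomes": genomes,
        "features": features,
        "te_library": te_lib,
        "ortholog_sets": osets,
        "truth": truth,
        "queries": queries,
        "run_config": RunConfig(simulation=cfg, neutrality_reps=200),
    }


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
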