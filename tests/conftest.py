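import numpy as np
import pandas as pd
import pytest

from gsconverge.genesets import GeneSet, GeneSetCollection
from gsconverge.synthetic_data import SimConfig, gen_gene_table


@pytest.fixture(scope="session")
def small_sim_config() -> SimConfig:
    """Desk-scale configuration used by unit tests that need a full cohort."""
    return SimConfig(
        n_genes=400,
        n_cell_types_human=3,
        n_cell_types_mouse=4,
        markers_per_type=30,
        synaptic_set_sizes=(50, 60),
        n_cases=500,
        n_controls=500,
        mu_ptv=2e-3,
        mu_syn=1e-2,
        seed=11,
    )


@pytest.fixture(scope="session")
def small_genes(small_sim_config) -> pd.DataFrame:
    return gen_gene_table(small_sim_config)


@pytest.fixture()
def toy_collection() -> GeneSetCollection:
    coll = GeneSetCollection()
    coll.add(GeneSet("PI", "PI", ("g1", "g2", "g3")))
    coll.add(GeneSet("cellA", "human_cell", ("g2", "g3", "g4", "g5")))
    coll.add(GeneSet("cellA_x_PI", "intersection", ("g2", "g3")))
    coll.add(GeneSet("brain_all", "background", ("g1", "g2", "g3", "g4", "g5", "g6")))
    return coll


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
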