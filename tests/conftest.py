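import numpy as np
import pandas as pd
import pytest

from metamodule.datatypes import StudyDataset
from metamodule.simulate import SimulationConfig, simulate_studies, simulate_network, network_graph


@pytest.fixture
def rng():
    return np.random.default_rng(20160125)


@pytest.fixture
def small_dataset(rng):
    """One 50-gene, 8+8-sample null study."""
    genes = [f"G{i:03d}" for i in range(50)]
    cols = [f"H{i}" for i in range(8)] + [f"L{i}" for i in range(8)]
    matrix = pd.DataFrame(rng.normal(7, 1, size=(50, 16)), index=genes, columns=cols)
    groups = pd.Series(["high"] * 8 + ["low"] * 8, index=cols)
    return StudyDataset("toy", matrix, groups)


@pytest.fixture(scope="session")
def planted_scene():
    """A small planted-module simulation shared by network-level tests."""
    config = SimulationConfig(
        k_studies=3, n_high=20, n_low=20, n_genes=400, deg_fraction=8 / 400,
        smd_range=(1.2, 1.2), heterogeneity_tau2=0.0, network_nodes=120,
        network_attach=2, planted_module_size=8, seed=99,
    )
    datasets, truth = simulate_studies(config)
    graph = network_graph(simulate_network(config, truth))
    return config, datasets, truth, graph
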