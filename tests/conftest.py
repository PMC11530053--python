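import numpy as np
import pytest

from adrank import (DecisionMatrix, MolecularGraph, bundled_drug_smiles,
                    edge_partition, graph_from_smiles, random_molecular_graph)

DONEPEZIL_SMILES = "COc1cc2c(cc1OC)C(=O)C(CC3CCN(CC3)Cc4ccccc4)C2"
DONEPEZIL_PARTITION = {(1, 2): 2, (1, 3): 1, (2, 2): 6, (2, 3): 18, (3, 3): 4}


@pytest.fixture(scope="session")
def donepezil():
    return graph_from_smiles(DONEPEZIL_SMILES, "donepezil")


@pytest.fixture(scope="session")
def donepezil_partition(donepezil):
    return edge_partition(donepezil)


@pytest.fixture(scope="session")
def drug_smiles_path():
    return bundled_drug_smiles()


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_random_graphs(n_graphs, seed=0, lo=4, hi=25, max_degree=4):
    rng = np.random.default_rng(seed)
    return [random_molecular_graph(int(rng.integers(lo, hi + 1)), max_degree,
                                   rng, id=f"g{i}") for i in range(n_graphs)]


def path_graph(n):
    return MolecularGraph.from_edges("path", [(f"v{i}", f"v{i+1}") for i in range(n - 1)])


def cycle_graph(n):
    return MolecularGraph.from_edges(
        "cycle", [(f"v{i}", f"v{(i + 1) % n}") for i in range(n)])


def star_graph(n_leaves):
    return MolecularGraph.from_edges("star", [("hub", f"leaf{i}") for i in range(n_leaves)])


def random_positive_matrix(m, n, seed):
    rng = np.random.default_rng(seed)
    return DecisionMatrix([f"A{i}" for i in range(m)], [f"C{j}" for j in range(n)],
                          rng.lognormal(0.0, 0.8, size=(m, n)))
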