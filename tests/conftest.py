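import numpy as np
import pytest

from mkphylo.matrix import CharacterMatrix
from mkphylo.simulate import GeneratingTreeSpec, SimulationConfig, assemble_matrix, make_generating_tree


def matrix_from_rows(taxa, rows, k=None):
    """Build a CharacterMatrix from strings like '0101?2'."""
    data = np.array([[-1 if c == "?" else int(c) for c in row] for row in rows],
                    dtype=np.int8)
    if k is None:
        k = [2 if data[:, j].max() <= 1 else 4 for j in range(data.shape[1])]
    return CharacterMatrix(list(taxa), data, np.asarray(k, dtype=np.int8))


@pytest.fixture(scope="session")
def symtree32():
    return make_generating_tree(GeneratingTreeSpec("symmetric", 32, 1.0))


@pytest.fixture(scope="session")
def asymtree32():
    return make_generating_tree(GeneratingTreeSpec("asymmetric", 32, 1.0))


@pytest.fixture(scope="session")
def asymtree6():
    return make_generating_tree(GeneratingTreeSpec("asymmetric", 6, 1.0))


@pytest.fixture(scope="session")
def matrix100(symtree32):
    return assemble_matrix(symtree32, SimulationConfig(n_chars=100, seed=11))
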