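import numpy as np
import pytest

from mcmda.io import AssociationMatrix, AssociationTable, build_adjacency
from mcmda.svt import SVTParams
from mcmda.synthetic import simulate


@pytest.fixture
def fast_params():
    """Small threshold so the iteration converges in a few dozen steps."""
    return SVTParams(tau=2.0)


@pytest.fixture
def tiny_instance():
    """20x15 rank-2 synthetic instance with 60% of the 1-entries observed."""
    return simulate(nm=20, nd=15, rank=2, density=0.2, observed_fraction=0.6, seed=3)


@pytest.fixture
def tiny_matrix(tiny_instance):
    return tiny_instance.observed


def matrix_from_pairs(pairs, nm, nd):
    """AssociationMatrix with synthetic names from explicit index pairs."""
    M = np.zeros((nm, nd))
    for i, j in pairs:
        M[i, j] = 1.0
    return AssociationMatrix(
        M,
        frozenset(pairs),
        tuple(f"m{i}" for i in range(nm)),
        tuple(f"d{j}" for j in range(nd)),
    )


@pytest.fixture
def assoc_file(tmp_path):
    """Factory writing an association list file and returning its path."""

    def make(lines, name="assoc.tsv"):
        path = tmp_path / name
        path.write_text("\n".join(lines) + "\n")
        return path

    return make
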