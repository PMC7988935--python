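import numpy as np
import pytest
import scipy.sparse as sp

from cactus import (
    AlleleCounts,
    ClonalData,
    CloneGenotypes,
    DistanceMatrix,
    InputClustering,
)


def make_data(
    omega: np.ndarray,
    A: np.ndarray,
    D: np.ndarray,
    cluster_index: np.ndarray,
    G: np.ndarray | None = None,
) -> ClonalData:
    """Assemble a ClonalData from dense arrays (no filtering)."""
    omega = np.asarray(omega)
    A, D = np.asarray(A), np.asarray(D)
    n, m = A.shape
    k = omega.shape[1]
    mut_ids = [f"chr1:{i + 1}:A:T" for i in range(n)]
    cell_ids = [f"c{j}" for j in range(m)]
    cluster_index = np.asarray(cluster_index)
    q = int(cluster_index.max()) + 1
    return ClonalData(
        genotypes=CloneGenotypes(mut_ids, [f"k{x}" for x in range(k)], omega),
        counts=AlleleCounts(mut_ids, cell_ids, sp.csr_matrix(A), sp.csr_matrix(D)),
        clustering=InputClustering(cell_ids, [f"q{x}" for x in range(q)], cluster_index),
        distances=DistanceMatrix(G) if G is not None else None,
    )


@pytest.fixture
def tiny_data() -> ClonalData:
    """2 clones, 2 mutations, 3 cells in 2 clusters, informative counts."""
    omega = np.array([[0, 1], [0, 1]])
    A = np.array([[3, 2, 0], [2, 0, 0]])
    D = np.array([[3, 2, 1], [2, 1, 2]])
    return make_data(omega, A, D, np.array([0, 0, 1]))


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
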