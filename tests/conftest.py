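"""Shared fixtures: small substitution matrices, trees and trait tables."""

import numpy as np
import pytest

from polymatrix import submat
from polymatrix.simulate import simulate_cluster


@pytest.fixture(scope="session")
def protein_matrix() -> submat.SubstitutionMatrix:
    """A full 20x20 log-odds matrix from synthetic high-identity clusters.

    Pseudocount 1 so every cell is informative (no floor values), which
    keeps alignment scores well-behaved in downstream tests.
    """
    clusters = [simulate_cluster(5, 300, 0.95, seed=s) for s in range(4)]
    return submat.build_matrix_pipeline(clusters, pseudocount=1.0)


@pytest.fixture(scope="session")
def toy_counts() -> submat.PairCounts:
    """Two-letter pair counts {AA: 6, AB: 2, BB: 2} (test alphabet)."""
    counts = np.array([[6.0, 2.0], [2.0, 2.0]])
    return submat.PairCounts(alphabet="AB", counts=counts)
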