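import numpy as np
import pytest
import scipy.sparse as sp

from satkit import ClusterAssignment, CountMatrix, QCParams, qc_filter, simulate
from satkit.simulate import BroadType, SimConfig


def separated_types(shift: float = 2.0) -> list[BroadType]:
    """Five broad types with strong, well-separated expression programs."""
    freqs = [0.30, 0.25, 0.20, 0.15, 0.10]
    return [BroadType(n, f, shift=shift) for n, f in zip("ABCDE", freqs)]


@pytest.fixture
def tiny_matrix() -> CountMatrix:
    """3 genes x 4 cells, hand-written counts."""
    counts = np.array(
        [
            [1, 0, 2, 5],
            [0, 3, 1, 0],
            [4, 1, 0, 2],
        ]
    )
    return CountMatrix(
        counts=sp.csc_matrix(counts),
        gene_names=["Foxg1", "Reln", "Lhx9"],
        barcodes=["AAA", "CCC", "GGG", "TTT"],
        library_labels=["l1", "l1", "l2", "l2"],
    )


@pytest.fixture(scope="session")
def sim5() -> CountMatrix:
    """Simulated matrix with 5 well-separated types, n = 2000, fixed seed."""
    cfg = SimConfig(n_cells=2000, n_genes=500, broad_types=separated_types(), seed=11)
    return simulate(cfg)


@pytest.fixture(scope="session")
def sim5_filtered(sim5) -> CountMatrix:
    matrix, _ = qc_filter(sim5, QCParams(min_genes=100))
    return matrix


def assignment(cells, labels, analysis_id="a") -> ClusterAssignment:
    return ClusterAssignment(cells=list(cells), labels=[str(l) for l in labels], analysis_id=analysis_id)
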