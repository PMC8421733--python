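import numpy as np
import pytest
import scipy.sparse as sp

from chdprio.core import CellMatrix, Lineage, mouse_gene


@pytest.fixture
def toy_matrix() -> CellMatrix:
    """6 genes x 6 cells, two clusters, with a selection-marker gene.

    Gene layout (rows): g0 is a clean cluster-A marker, g1 uniform, g2 a
    cluster-B marker, g3 silent except one cell, g4 background, NeoR positive
    in cells 1 and 3.
    """
    counts = np.array(
        [
            [5, 4, 6, 0, 0, 1],   # g0: high in A (cells 0-2)
            [2, 2, 2, 2, 2, 2],   # g1: identical everywhere
            [0, 1, 0, 7, 5, 6],   # g2: high in B (cells 3-5)
            [0, 0, 1, 0, 0, 0],   # g3: nearly silent
            [1, 2, 1, 2, 1, 2],   # g4: background
            [0, 3, 0, 2, 0, 0],   # NeoR
        ]
    )
    return CellMatrix(
        counts=sp.csr_matrix(counts),
        gene_ids=[mouse_gene(s) for s in ["Ga", "Gb", "Gc", "Gd", "Ge", "NeoR"]],
        cell_ids=[f"c{i}" for i in range(6)],
        cluster_labels=["A", "A", "A", "B", "B", "B"],
        lineage_of_cluster={"A": Lineage.MESENCHYMAL, "B": Lineage.BLOOD},
    )
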