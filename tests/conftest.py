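import numpy as np
import pytest
import scipy.sparse as sp

from lactoscore.io import CountMatrix, GeneSet


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_counts(rng):
    """20 cells x 12 genes of Poisson counts, two genes mitochondrial."""
    genes = [f"MT-{i}" for i in range(2)] + [f"G{i:02d}" for i in range(10)]
    counts = rng.poisson(3.0, size=(20, 12))
    return CountMatrix(
        values=sp.csr_matrix(counts),
        cell_ids=[f"c{i:02d}" for i in range(20)],
        gene_ids=genes,
    )


@pytest.fixture
def toy_gene_set():
    return GeneSet(name="toy", genes=["G00", "G01", "G02"])


def ranks_from_placement(n: int, set_ranks: tuple[int, ...]) -> np.ndarray:
    """Rank vector for all n genes where genes 0..len(set_ranks)-1 occupy the
    given (distinct, 1-based) ranks and the rest fill the remaining ranks."""
    other = [r for r in range(1, n + 1) if r not in set_ranks]
    return np.array(list(set_ranks) + other, dtype=float)
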