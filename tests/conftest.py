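import numpy as np
import pytest

from dupepi.genotypes import MISSING, GenotypeMatrix


def make_matrix(cells, populations=None, loci=None):
    """Build a GenotypeMatrix from a nested list of (a, b) pairs.

    ``cells[i][j]`` is a 2-tuple of allele labels or None for missing.
    """
    n_ind = len(cells)
    n_loci = len(cells[0])
    individuals = [f"ind{i+1}" for i in range(n_ind)]
    if populations is None:
        populations = ["pop1"] * n_ind
    if loci is None:
        loci = [f"L{j+1}" for j in range(n_loci)]
    data = np.full((n_ind, n_loci, 2), MISSING, dtype=np.int64)
    for i, row in enumerate(cells):
        for j, cell in enumerate(row):
            if cell is not None:
                data[i, j] = cell
    return GenotypeMatrix(individuals, populations, loci, data)


@pytest.fixture
def two_pop_matrix():
    """2 populations x 2 individuals x 2 loci, fully typed."""
    return make_matrix(
        [
            [(100, 105), (200, 200)],
            [(100, 100), (200, 205)],
            [(105, 110), (205, 205)],
            [(110, 110), (200, 210)],
        ],
        populations=["pop1", "pop1", "pop2", "pop2"],
    )
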