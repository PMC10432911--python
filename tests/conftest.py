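import numpy as np
import pytest

from tophapplus.genotype_io import GenotypeMatrix, MISSING, MUT, WILD


@pytest.fixture
def coi_fixture_matrix() -> GenotypeMatrix:
    """10-cell matrix over sites a, d: 8 carriers of d, 6 of which carry a."""
    rows = []
    for i in range(10):
        d = MUT if i < 8 else WILD
        a = MUT if i < 6 else WILD
        rows.append([a, d])
    return GenotypeMatrix([f"c{i}" for i in range(10)], ["a", "d"],
                          np.array(rows, dtype=np.int8))


@pytest.fixture
def chain_matrix() -> GenotypeMatrix:
    """Three nested clones (s1) < (s1,s2) < (s1,s2,s3), 8 cells each, no noise."""
    clones = {
        "A": [1, 0, 0],
        "B": [1, 1, 0],
        "C": [1, 1, 1],
    }
    cells, rows = [], []
    for name, g in clones.items():
        for k in range(8):
            cells.append(f"{name}{k}")
            rows.append(g)
    return GenotypeMatrix(cells, ["s1", "s2", "s3"], np.array(rows, dtype=np.int8))
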