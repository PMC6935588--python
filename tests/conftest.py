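import numpy as np
import pandas as pd
import pytest

from hzmove.core import GenotypeMatrix


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)


@pytest.fixture()
def small_pops():
    """Six populations on a straight 500-km south-to-north line."""
    lats = np.array([20.0, 21.0, 22.0, 23.0, 24.0, 25.0])
    return pd.DataFrame(
        {
            "pop_id": [f"P{i}" for i in range(6)],
            "lat": lats,
            "lon": np.full(6, -105.0),
            "group": ["speciesA", "speciesA", "hybrid", "hybrid", "speciesB", "speciesB"],
        }
    )


@pytest.fixture()
def tiny_matrix():
    """Four individuals x three loci with one missing call, phased."""
    geno = np.array([[0, 1, 2], [2, 1, 0], [1, 1, 1], [2, -1, 0]], dtype=np.int8)
    haps = np.zeros((4, 2, 3), dtype=np.int8)
    for i in range(4):
        for j in range(3):
            g = geno[i, j]
            if g == 1:
                haps[i, 0, j] = 1
            elif g == 2:
                haps[i, :, j] = 1
    haps[3, :, 1] = 0
    return GenotypeMatrix(
        geno,
        ["P0_i1", "P0_i2", "P1_i1", "P1_i2"],
        ["snp1", "snp2", "snp3"],
        np.array(["P0", "P0", "P1", "P1"], dtype=object),
        None,
    )
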