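import numpy as np
import pandas as pd
import pytest

from cropwild.genio import MISSING, GenotypeMatrix, PopulationMap


def make_gm(dosage, depth=None, sample_ids=None, chrom="chr1"):
    """Small genotype matrix from a nested list (rows = samples)."""
    dosage = np.asarray(dosage, dtype=np.int16)
    n, m = dosage.shape
    if depth is None:
        depth = np.where(dosage == MISSING, 0, 100)
    sample_ids = sample_ids or [f"s{i}" for i in range(n)]
    sites = pd.DataFrame(
        {"chrom": chrom, "pos": np.arange(1, m + 1) * 10, "ref": "A", "alt": "T"}
    )
    return GenotypeMatrix(sample_ids, sites, dosage, np.asarray(depth))


@pytest.fixture
def toy_two_pop():
    """Six + six diploids at three hand-written sites (columns)."""
    dosA = [[0, 1, 2], [1, 0, 2], [1, 1, 2], [2, 0, 2], [2, 1, 2], [2, 1, 2]]
    dosB = [[0, 0, 0], [0, 1, 0], [0, 0, 0], [1, 2, 0], [1, 1, 0], [0, 0, 0]]
    gm = make_gm(np.vstack([dosA, dosB]))
    pm = PopulationMap(
        {f"s{i}": ("A" if i < 6 else "B") for i in range(12)},
        roles={"A": "pure1", "B": "pure2"},
    )
    return gm, pm, dosA, dosB
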