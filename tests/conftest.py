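import numpy as np
import pandas as pd
import pytest

from chipeval.io import GenotypeTable
from chipeval.simulate import four_line_scenario


def make_table(dosages, lines=None, chrom="1", positions=None, sample_ids=None):
    """Small GenotypeTable from a dense array (rows = samples)."""
    d = np.asarray(dosages, dtype=float)
    n, m = d.shape
    if positions is None:
        positions = np.arange(1, m + 1) * 100
    if sample_ids is None:
        sample_ids = [f"s{i}" for i in range(n)]
    if lines is None:
        lines = ["L"] * n
    variants = pd.DataFrame(
        {"chrom": chrom, "pos": positions, "ref": "A", "alt": "G"}
    )
    return GenotypeTable(d, variants, sample_ids, list(lines))


@pytest.fixture(scope="session")
def small_scenario():
    """Reduced four-line scenario shared across tests (dense, chip, map, truth)."""
    return four_line_scenario(seed=11, n_markers=6000, n_chip_markers=1000)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
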