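import numpy as np
import pandas as pd
import pytest

from mrmediate.harmonize import from_arrays
from mrmediate.sumstats import COLUMNS, TraitTable


def make_trait(rows, trait_id="T", trait_type="exposure") -> TraitTable:
    """Build a TraitTable from (snp, chrom, pos, ea, oa, eaf, beta, se, p, n)
    tuples without going through file I/O."""
    df = pd.DataFrame(rows, columns=COLUMNS)
    df["pos"] = pd.array(df["pos"], dtype="Int64")
    df["n"] = pd.array(df["n"], dtype="Int64")
    return TraitTable(trait_id, trait_type, df)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def proportional_set():
    """Five instruments lying exactly on by = 0.3*bx."""
    bx = np.array([0.1, 0.15, 0.2, 0.25, 0.3])
    return from_arrays(bx, np.full(5, 0.001), 0.3 * bx, np.full(5, 0.01))


def random_harmonized(rng, k=None):
    k = k or int(rng.integers(3, 12))
    bx = rng.normal(0, 0.3, k)
    bx[np.abs(bx) < 0.01] = 0.05
    se_x = rng.uniform(0.005, 0.05, k)
    by = rng.normal(0, 0.2, k)
    se_y = rng.uniform(0.005, 0.05, k)
    return from_arrays(bx, se_x, by, se_y)
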