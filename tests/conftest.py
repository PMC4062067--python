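import numpy as np
import pandas as pd
import pytest

import orfscreen as o


@pytest.fixture
def small_library():
    return o.make_library(n_orfs=20, pool_size=8, seed=0)


@pytest.fixture
def uniform_library():
    """Ten ORFs, all 1000 nt (degenerate lengths for trend tests)."""
    lib = o.make_library(n_orfs=10, pool_size=10, seed=0)
    lib["length_nt"] = 1000
    return lib


def make_enrichment(values):
    """Build an enrichment table from {orf_id: (x, y)}."""
    return pd.DataFrame(
        {"x": [v[0] for v in values.values()],
         "y": [v[1] for v in values.values()]},
        index=pd.Index(values.keys(), name="orf_id"),
    )


@pytest.fixture
def enrichment_factory():
    return make_enrichment
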