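import numpy as np
import pandas as pd
import pytest

import receptorsig as rs


def make_matrix(values, probes=None, samples=None, platform="test"):
    values = np.asarray(values, dtype=float)
    probes = probes or [f"p{i}" for i in range(values.shape[0])]
    samples = samples or [f"s{i}" for i in range(values.shape[1])]
    return rs.ExpressionMatrix(pd.DataFrame(values, index=probes, columns=samples), platform)


def make_clinical(statuses, samples=None, receptor="ER", assay="IHC"):
    samples = samples or [f"s{i}" for i in range(len(statuses))]
    return rs.ClinicalTable(pd.Series(list(statuses), index=samples), receptor, assay)


@pytest.fixture
def tiny_matrix():
    return make_matrix([[1, 2, 3, 4], [4, 3, 2, 1], [5, 5, 5, 5]], probes=["a", "b", "c"])


@pytest.fixture
def synthetic_pair():
    """Two independently seeded planted datasets sharing one config shape."""
    cfg1 = rs.SyntheticConfig(n_samples=200, n_background=300, seed=11)
    cfg2 = rs.SyntheticConfig(n_samples=200, n_background=300, seed=100011)
    return rs.generate(cfg1), rs.generate(cfg2)
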