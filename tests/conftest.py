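import numpy as np
import pandas as pd
import pytest

from brushmeth.methcall import MethylationMatrix
from brushmeth.synthdata import generate_panel, simulate_profile


@pytest.fixture(scope="session")
def small_panel():
    """3 amplicons, 12 CpGs, length 80 — fast enough for alignment loops."""
    return generate_panel(n_genes=3, total_cpgs=12, amplicon_length=80, seed=42)


@pytest.fixture(scope="session")
def full_panel():
    """The default 13-gene / 243-CpG panel."""
    return generate_panel(n_genes=13, total_cpgs=243, amplicon_length=300, seed=7)


@pytest.fixture
def tumor_profile(small_panel):
    return simulate_profile(small_panel, "tumor", seed=1)


def make_matrix(X, cpg_ids=None, sample_ids=None, coverage=100):
    """Wrap a 2-D array as a MethylationMatrix with constant coverage."""
    X = np.asarray(X, dtype=float)
    cpg_ids = cpg_ids or [f"g:{i}" for i in range(X.shape[1])]
    sample_ids = sample_ids or [f"s{i}" for i in range(X.shape[0])]
    ratios = pd.DataFrame(X, index=sample_ids, columns=cpg_ids)
    cov = pd.DataFrame(
        np.full(X.shape, coverage, dtype=int), index=sample_ids, columns=cpg_ids
    )
    cov[ratios.isna()] = 0
    return MethylationMatrix(ratios, cov)


@pytest.fixture
def separable_matrix():
    """20 samples x 12 CpGs, tumor-high / healthy-low, well separated."""
    rng = np.random.default_rng(0)
    X = np.vstack([rng.beta(1.5, 10, (10, 12)), rng.beta(8, 2, (10, 12))])
    labels = np.array([0] * 10 + [1] * 10)
    return make_matrix(X), labels
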