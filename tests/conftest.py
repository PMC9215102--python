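import numpy as np
import pytest

from supertax import OtuTable, SampleMetadata
from supertax.depth_forest import ForestParams


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture()
def small_forest_params():
    return ForestParams(n_trees=20, min_node_size=5, seed=3)


def planted_block(n=120, n_otus=6, n_true=2, effect=0.8, seed=0):
    """A small block where the first `n_true` OTUs are enriched in cases.

    Sparse gamma counts; case samples get their true-OTU abundances
    scaled by exp(effect) and their presence probability raised.
    """
    r = np.random.default_rng(seed)
    y = np.zeros(n, dtype=int)
    y[n // 2:] = 1
    present = r.random((n, n_otus)) < 0.45
    vals = np.round(r.gamma(2.0, 8.0, (n, n_otus))) + 1
    X = vals * present
    boost = r.random((n, n_true)) < 0.35
    X[:, :n_true] = np.where((y[:, None] == 1) & boost,
                             np.maximum(X[:, :n_true], 1) * np.exp(effect),
                             X[:, :n_true])
    return X.astype(float), y


@pytest.fixture()
def planted(request):
    return planted_block()


@pytest.fixture()
def toy_cohort():
    """40-sample cohort with one strongly associated 3-OTU genus block
    and two null blocks, as a dense count table + metadata."""
    r = np.random.default_rng(11)
    n = 40
    y = np.array([0, 1] * (n // 2))
    X = np.round(r.gamma(1.0, 20.0, (n, 9)) * (r.random((n, 9)) < 0.6))
    # block 0 = columns 0-2: OTU 0 is a near-perfect marker
    X[:, 0] = np.where(y == 1, np.round(r.gamma(3.0, 15.0, n)) + 5, 0.0)
    X += 1e0 * 0  # keep counts
    sample_ids = [f"s{i}" for i in range(n)]
    otu_ids = [f"otu{j}" for j in range(9)]
    table = OtuTable(X, sample_ids, otu_ids, scale="counts")
    meta = SampleMetadata(sample_ids, y)
    blocks = {"genusA": [0, 1, 2], "genusB": [3, 4, 5], "genusC": [6, 7, 8]}
    return table, meta, blocks
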