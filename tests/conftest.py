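import numpy as np
import pandas as pd
import pytest

from gdtec import GeneSampleMatrix, SyntheticSpec, generate


def make_matrix(arr, domain="real", genes=None, samples=None) -> GeneSampleMatrix:
    arr = np.asarray(arr, dtype=float)
    genes = genes or [f"g{i}" for i in range(arr.shape[0])]
    samples = samples or [f"s{j}" for j in range(arr.shape[1])]
    return GeneSampleMatrix(pd.DataFrame(arr, index=genes, columns=samples), domain)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort shared by tests that only read from it."""
    return generate(SyntheticSpec(seed=42))


@pytest.fixture(scope="session")
def perfect_blocks():
    """Binary matrix with four perfectly separated sample blocks."""

    def build(n_blocks: int, n_samples: int = 80, n_genes: int = 40):
        labels = np.repeat(np.arange(n_blocks), n_samples // n_blocks)
        M = np.zeros((n_genes, n_samples))
        per = n_genes // n_blocks
        for b in range(n_blocks):
            M[b * per : (b + 1) * per, labels == b] = 1.0
        return make_matrix(M, "binary"), labels

    return build
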