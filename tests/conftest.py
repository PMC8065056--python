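import numpy as np
import pytest

from nagwas.io import GenotypeProbabilityMatrix, VariantKey


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_matrix(rng, n_samples=8, n_variants=5, chrom="1"):
    """Random well-formed probability matrix for round-trip tests."""
    raw = rng.dirichlet([1.0, 1.0, 1.0], size=(n_samples, n_variants))
    variants = [
        VariantKey(chrom, 1000 * (j + 1), f"rs{j + 1}", "A", "G")
        for j in range(n_variants)
    ]
    samples = [f"sample_{i + 1}" for i in range(n_samples)]
    return GenotypeProbabilityMatrix(variants, samples, raw)


@pytest.fixture
def small_matrix(rng):
    return random_matrix(rng)
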