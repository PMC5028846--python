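import numpy as np
import pytest

from kronfuse import GeneratorConfig, generate
from kronfuse.containers import SimilarityMatrix
from kronfuse.pipeline import bundle_labels, bundle_similarities


@pytest.fixture(scope="session")
def small_bundle():
    """40 cells x 12 drugs: big enough for CV, quick to evaluate."""
    return generate(GeneratorConfig(n_cells=40, n_drugs=12, seed=1))


@pytest.fixture(scope="session")
def small_fused(small_bundle):
    cells, drugs = bundle_similarities(small_bundle)
    labels = bundle_labels(small_bundle)
    return cells, drugs, labels


def random_similarity(rng, n):
    """A valid random SimilarityMatrix (symmetric PSD-ish, unit diagonal)."""
    x = rng.normal(size=(n, max(2, n // 2)))
    d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(-1)
    v = np.exp(-d2 / max(d2.mean(), 1e-9))  # Gaussian kernel: PSD, in (0, 1]
    np.fill_diagonal(v, 1.0)
    return SimilarityMatrix([f"e{i}" for i in range(n)], v)
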