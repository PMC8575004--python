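import numpy as np
import pytest

from sfstrat.io_formats import AffinityTable, FeatureTable
from sfstrat.similarity import SimilarityMatrix
from sfstrat.synthetic import SynthConfig, generate_benchmark


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def toy_similarity():
    """2 test x 4 train similarity matrix with hand-checkable nested sets."""
    return SimilarityMatrix(
        test_ids=["qa01", "qa02"],
        train_ids=["ta01", "ta02", "ta03", "ta04"],
        values=np.array([[0.3, 0.5, 0.95, 1.0],
                         [0.2, 0.6, 0.4, 0.9]]),
        kind="similarity",
        metric_name="protein_structure",
    )


@pytest.fixture(scope="session")
def small_benchmark():
    """A small but fully structured synthetic benchmark (shared, read-only)."""
    return generate_benchmark(
        SynthConfig(n_train=400, n_test=80, n_clusters=12, seed=7)
    )


def random_similarity_matrix(rng, n_test, n_train, kind):
    values = rng.random((n_test, n_train))
    if kind == "dissimilarity":
        values = values * 12.0
    return SimilarityMatrix(
        test_ids=[f"q{i:03x}" for i in range(n_test)],
        train_ids=[f"t{i:03x}" for i in range(n_train)],
        values=values,
        kind=kind,
    )


def linear_table(rng, n, columns, weights, intercept=0.0, noise=0.0):
    """A feature table plus affinities from an exact linear model."""
    X = rng.normal(size=(n, len(columns)))
    y = intercept + X @ np.asarray(weights) + noise * rng.normal(size=n)
    ids = [f"x{i:03x}" for i in range(n)]
    return FeatureTable(ids, list(columns), X), AffinityTable(dict(zip(ids, y)))
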