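import numpy as np
import pytest

from protofam import (
    E_CAP,
    E_FLOOR,
    SimilarityMatrix,
    StabilityParams,
    SyntheticSpec,
    build_tree,
    gen_similarity,
    stable_clusters,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230211)


def random_similarity(rng, n, lo=-40.0, hi=1.9):
    """A random symmetric capped matrix with log-uniform entries."""
    expo = rng.uniform(lo, hi, size=(n, n))
    values = 10.0 ** expo
    values = np.minimum(np.triu(values, 1) + np.triu(values, 1).T, E_CAP)
    values[values == 0] = E_CAP
    np.fill_diagonal(values, E_FLOOR)
    return SimilarityMatrix([f"p{i}" for i in range(n)], values)


@pytest.fixture(scope="session")
def small_planted():
    """A small planted-family dataset with its clustering artifacts.

    Enough families that even the youngest completed family outlives the
    default LifeTime pruning threshold.
    """
    spec = SyntheticSpec(n_families=18, family_size_range=(4, 8), orphan_fraction=0.05)
    m, truth = gen_similarity(spec, 42)
    params = StabilityParams()
    tree = build_tree(m, params)
    stable = stable_clusters(tree, params)
    return spec, m, truth, tree, stable, params
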