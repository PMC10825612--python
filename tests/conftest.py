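import numpy as np
import pytest

import marrowsect as ms


@pytest.fixture(scope="session")
def small_corpus():
    """A 60-report synthetic corpus for fast unit tests."""
    return ms.generate_corpus(ms.GeneratorConfig(n_reports=60, seed=11))


@pytest.fixture(scope="session")
def small_split(small_corpus):
    return ms.chronological_split(small_corpus, 0.8)


@pytest.fixture(scope="session")
def default_grid_result(tmp_path_factory):
    """The full default experiment grid on the default 500-report corpus.

    Shared across the acceptance tests so the grid runs once per session.
    """
    config = ms.ExperimentConfig(
        generator=ms.GeneratorConfig(n_reports=500, seed=7), seed=7
    )
    out_dir = tmp_path_factory.mktemp("default_grid")
    result = ms.run_experiment(config, out_dir=out_dir)
    return config, result, out_dir


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_binary_vectors(rng, n, d):
    return rng.integers(0, 2, size=(n, d)).astype(float)
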