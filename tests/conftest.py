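import numpy as np
import pytest

from netmark import (
    SyntheticConfig,
    binarize_density,
    detect_communities,
    generate_cohort,
    weighted_graph,
)


@pytest.fixture(scope="session")
def small_cohort():
    """Tiny low-noise cohort with a strong planted anti-coupling on regions
    (1, 2); shared by tests that only need plausible pipeline inputs."""
    cfg = SyntheticConfig(grid_dims=(4, 4, 4), n_true_regions=3,
                          n_timepoints=60, n_controls=6, n_patients=6,
                          planted_effects=[(1, 2, -0.5)],
                          voxel_noise_sd=0.5, seed=11)
    datasets, truth = generate_cohort(cfg)
    return cfg, datasets, truth


@pytest.fixture()
def demo_graph():
    """An 8-node correlation graph, binarized at 30% density with a
    community partition, for measure-level tests."""
    rng = np.random.default_rng(5)
    x = rng.standard_normal((80, 8))
    x[:, 1] += x[:, 0]
    x[:, 3] += x[:, 2]
    g = weighted_graph(x)
    binarize_density(g, 0.30)
    detect_communities(g, seed=0)
    return g


def random_binary_graph(k, rng, p=0.4):
    a = (rng.random((k, k)) < p).astype(int)
    a = np.triu(a, 1)
    return a + a.T
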