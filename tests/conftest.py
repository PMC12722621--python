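import numpy as np
import pytest

import shortcut_audit as sa


@pytest.fixture(scope="session")
def small_config() -> sa.PhantomConfig:
    return sa.PhantomConfig(
        grid_shape=(16, 16, 16),
        n_subjects_per_class=10,
        images_per_subject=1,
        atrophy_effect=0.1,
        noise_sd=0.02,
        seed=123,
    )


@pytest.fixture(scope="session")
def small_cohort(small_config) -> sa.PhantomCohort:
    return sa.generate_cohort(small_config)


@pytest.fixture(scope="session")
def phantom_pair(small_cohort):
    """One (volume, mask, labels) triple from the small cohort."""
    im = small_cohort.images[0]
    return im.volume, im.mask, im.labels


@pytest.fixture(scope="session")
def tiny_network():
    """An untrained 16-cubed network with a fixed initialization."""
    spec = sa.NetworkSpec(input_shape=(16, 16, 16))
    return sa.build_network(spec, np.random.default_rng(42))


@pytest.fixture(scope="session")
def separable_data():
    """Two constant-intensity classes, linearly separable, at 16-cubed."""
    rng = np.random.default_rng(7)
    n = 20
    lo = rng.normal(0.3, 0.02, size=(n, 16, 16, 16)).clip(0)
    hi = rng.normal(0.7, 0.02, size=(n, 16, 16, 16)).clip(0)
    x = np.concatenate([lo, hi]).astype(np.float32)
    y = np.array([0] * n + [1] * n)
    order = rng.permutation(2 * n)
    return x[order], y[order]
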