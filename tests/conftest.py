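import numpy as np
import pytest

import focusradiomics as fr


@pytest.fixture(scope="session")
def small_cfg():
    """Fast motion-free cohort configuration used across tests."""
    return fr.CohortConfig(n_benign=3, n_malignant=3,
                           volume_shape=(16, 24, 24), seed=123)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return fr.generate_cohort(small_cfg)


@pytest.fixture(scope="session")
def one_case(small_cohort):
    return small_cohort[0]


@pytest.fixture(scope="session")
def malignant_case(small_cohort):
    return next(c for c in small_cohort if c.label == fr.MALIGNANT)


@pytest.fixture(scope="session")
def feature_table(small_cohort):
    return fr.extract_cohort(small_cohort)


def random_quantized_roi(rng, max_side=5, n_levels=4):
    """Random small QuantizedROI with a random (nonempty) mask."""
    from focusradiomics.features import QuantizedROI

    shape = tuple(rng.integers(2, max_side + 1, size=3))
    mask = rng.random(shape) < 0.7
    if not mask.any():
        mask[tuple(rng.integers(0, s) for s in shape)] = True
    levels = np.zeros(shape, dtype=np.int64)
    levels[mask] = rng.integers(1, n_levels + 1, size=int(mask.sum()))
    return QuantizedROI(levels, n_levels, mask, (1.0, 1.0, 1.0))
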