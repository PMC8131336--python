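import numpy as np
import pytest

from lsvar import CohortConfig, generate_cohort, score_patient


@pytest.fixture(scope="session")
def default_cohort():
    """One default synthetic cohort (141 patients, seed 0)."""
    return generate_cohort(CohortConfig(seed=0))


@pytest.fixture(scope="session")
def default_panels(default_cohort):
    return [score_patient(r) for r in default_cohort]


@pytest.fixture(scope="session")
def default_labels(default_cohort):
    return np.array([r.is_positive() for r in default_cohort])


def random_roc_instance(rng, max_n=50):
    """A random scores/labels instance with ties and both classes present."""
    n = int(rng.integers(4, max_n + 1))
    # coarse grid forces ties between and within classes
    scores = rng.integers(0, max(2, n // 3), size=n).astype(float)
    labels = np.zeros(n, dtype=bool)
    n_pos = int(rng.integers(1, n))
    labels[rng.choice(n, size=n_pos, replace=False)] = True
    return scores, labels
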