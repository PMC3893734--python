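import numpy as np
import pytest

from plssubtype import (SimulationSpec, generate_cohort, load_pam50_panels,
                        standardize_genes)


@pytest.fixture(scope="session")
def panels():
    return load_pam50_panels()


@pytest.fixture(scope="session")
def small_cohort():
    """Well-separated 5-subtype cohort, 12 samples each, for classifier tests."""
    spec = SimulationSpec(seed=20260929, n_per_subtype=(12,) * 5,
                          effect_size=3.0, noise_sd=1.0)
    matrix, labels = generate_cohort(spec)
    return matrix, np.array(labels)


@pytest.fixture(scope="session")
def small_cohort_std(small_cohort):
    matrix, labels = small_cohort
    return standardize_genes(matrix).matrix, labels
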