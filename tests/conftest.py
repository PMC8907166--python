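import numpy as np
import pytest

from multipred import synthcohort as sc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """Small cohort with a real planted signal, shared across read-only tests."""
    cfg = sc.SynthConfig(
        n_subjects=120,
        n_clinical=20,
        n_informative=2,
        effect_vector=np.array([1.2, 1.0]),
        n_voxels=150,
        seed=7,
    )
    return cfg, sc.generate_cohort(cfg)
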