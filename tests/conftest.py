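import numpy as np
import pytest

from strifun import _engine


@pytest.fixture(scope="session", autouse=True)
def _warm_kernels():
    """Compile the numba likelihood kernels once per test session."""
    _engine.warmup()


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_cohort():
    """A compact planted cohort shared by the structure-function tests."""
    from strifun.synthetic_neuro import CohortConfig, generate_cohort

    cfg = CohortConfig(n_subjects=10, n_voxels=150, n_targets=40,
                       contrasts=("reward",), n_empty_targets=1)
    return generate_cohort(cfg, seed=7)
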