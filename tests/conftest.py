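import numpy as np
import pytest

from gradvar.cohort import CohortConfig, simulate_cohort
from gradvar.mesh import build_mesh


@pytest.fixture(scope="session")
def mesh_small():
    """Tiny 6x7 grid (42 vertices) for fast structural tests."""
    return build_mesh(6, 7, 1.0)


@pytest.fixture(scope="session")
def mesh_default():
    """The 500-vertex grid used as the standard synthetic surface."""
    return build_mesh(20, 25, 4.0)


@pytest.fixture(scope="session")
def cohort_small(mesh_small):
    """Small cohort (12 subjects, 2 short runs) with default planted structure."""
    config = CohortConfig(
        n_subjects=12, runs=(30, 30), cluster_n_vertices=8, seed=7
    )
    subjects, behavior, truth = simulate_cohort(mesh_small, config)
    return config, subjects, behavior, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
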