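import numpy as np
import pytest

from twinreg import datasets
from twinreg.estimation import ComponentModelSpec
from twinreg.simulate import simulate_twins


@pytest.fixture(scope="session")
def children_components():
    return datasets.children_components()


@pytest.fixture(scope="session")
def adult_components():
    return datasets.adult_components()


@pytest.fixture(scope="session")
def children_spec():
    return ComponentModelSpec.children_adce()


@pytest.fixture(scope="session")
def small_children_data():
    """A small simulated children cohort with mixed missingness."""
    cfg = datasets.children_simulation_config(seed=42, n_mz=80, n_dz=100)
    cfg.missingness = {"aggression": 0.15, "hyperactivity": 0.25, "inattention": 0.1}
    data, truth = simulate_twins(cfg)
    return data, truth


def random_pd_matrix(rng, dim=3, scale=1.0):
    a = rng.standard_normal((dim, dim))
    return scale * (a @ a.T + dim * np.eye(dim) * 0.1)
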