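import numpy as np
import pytest

import shapescission as sc


@pytest.fixture
def small_afc_design():
    return sc.afc_design(n_observers=4, n_exemplars=6)


@pytest.fixture
def small_rating_design():
    return sc.rating_design("material", n_observers=4, n_exemplars_used=3)


@pytest.fixture
def small_naming_design():
    return sc.naming_design(n_observers=4)


@pytest.fixture
def identity_kernels(small_afc_design):
    return sc.make_default_kernels(small_afc_design, accuracy=1.0, confusability=0.0)


@pytest.fixture
def afc_trials(small_afc_design):
    kern = sc.make_default_kernels(small_afc_design, accuracy=0.8,
                                   confusability=0.15,
                                   material_modulation={"wire": 2.0})
    obs = sc.make_observers(kern, small_afc_design.n_observers,
                            lapse_rate=0.02, observer_jitter_sd=0.2, seed=11)
    return sc.simulate_afc(small_afc_design, obs, seed=12)


@pytest.fixture
def rating_trials(small_rating_design):
    kern = sc.make_default_kernels(small_rating_design, "material", accuracy=0.85)
    obs = sc.make_observers(kern, small_rating_design.n_observers,
                            rating_noise_sd=0.08, observer_jitter_sd=0.2, seed=21)
    return sc.simulate_rating(small_rating_design, obs, seed=22)


@pytest.fixture
def random_cells():
    """Balanced 8-subject 3x4 cell-means table with subject offsets."""
    rng = np.random.default_rng(42)
    y = rng.normal(0.7, 0.1, size=(8, 3, 4)) + rng.normal(0, 0.05, size=(8, 1, 1))
    y = np.clip(y, 0, 1)
    return sc.CellMeansTable(
        tuple(f"o{i}" for i in range(8)),
        ("m0", "m1", "m2"), ("t0", "t1", "t2", "t3"), y)
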