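"""Shared fixtures: small simulated datasets and fitted models.

The heavy fits are session-scoped so several test modules can reuse
them.
"""

import numpy as np
import pytest

from purecall import JointSomaticModel, PriorConfig
from purecall.simulate import SimConfig, simulate_counts


@pytest.fixture(scope="session")
def small_sim():
    """Two-sample diploid dataset, purities (0.25, 0.55) at 100X."""
    return simulate_counts(SimConfig(purities=(0.25, 0.55),
                                     coverage=(100, 100), n_somatic=100,
                                     n_germline_het=1000, seed=1))


@pytest.fixture(scope="session")
def small_fit(small_sim):
    return JointSomaticModel.from_simulation(small_sim).fit(seed=1)


@pytest.fixture(scope="session")
def recovery_sim():
    """Two-sample diploid dataset with purities (0.25, 0.60) at 200X,
    200 somatic and 2,000 germline het sites."""
    return simulate_counts(SimConfig(purities=(0.25, 0.60),
                                     coverage=(200, 200), n_somatic=200,
                                     n_germline_het=2000, seed=3))


@pytest.fixture(scope="session")
def recovery_fit(recovery_sim):
    return JointSomaticModel.from_simulation(recovery_sim).fit(seed=3)


@pytest.fixture()
def cfg():
    return PriorConfig()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
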