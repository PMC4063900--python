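import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from oligoims import (
    AB40_SEQUENCE,
    average_mass,
    composition_from_sequence,
    load_table1,
)

settings.register_profile(
    "suite",
    deadline=None,
    max_examples=30,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ab40_composition():
    return composition_from_sequence(AB40_SEQUENCE)


@pytest.fixture(scope="session")
def monomer_avg_mass(ab40_composition):
    return average_mass(ab40_composition)


@pytest.fixture(scope="session")
def table1():
    return load_table1()


@pytest.fixture(scope="session")
def table1_mass_outliers():
    """Cells of the published table whose printed mass is internally
    inconsistent with the printed m/z (typo / last-digit rounding)."""
    return {(3, 7, 10.14), (3, 7, 8.36)}  # (n, z, tD_A)


def gaussian(x, mu, sigma):
    return np.exp(-0.5 * ((x - mu) / sigma) ** 2)
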