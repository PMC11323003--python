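import numpy as np
import pytest
from hypothesis import settings

from lipodna.traj_analysis import Frame

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture
def ideal_gas_frame(rng):
    """1000 uncorrelated neutral particles in a cubic box."""
    box = np.array([8.0, 8.0, 8.0])
    n = 1000
    return Frame(
        positions=rng.uniform(0, 1, (n, 3)) * box,
        species=np.array(["GAS"] * n, dtype=object),
        charges=np.zeros(n),
        box=box,
    )


def random_charged_frame(rng, n=120, box=(6.0, 5.0, 4.0)):
    """Small random frame mixing all species the censuses care about."""
    box = np.asarray(box, dtype=float)
    labels = ["DNA_P", "MG", "CL", "PC_N", "PC_OP", "PC_O", "TAP_N", "TAP_O"]
    charge_of = {"DNA_P": -1, "MG": 2, "CL": -1, "PC_N": 1, "PC_OP": -1,
                 "PC_O": 0, "TAP_N": 1, "TAP_O": 0}
    species = rng.choice(labels, size=n)
    return Frame(
        positions=rng.uniform(0, 1, (n, 3)) * box,
        species=species.astype(object),
        charges=np.array([charge_of[s] for s in species], dtype=float),
        box=box,
    )


@pytest.fixture
def charged_frame(rng):
    return random_charged_frame(rng)
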