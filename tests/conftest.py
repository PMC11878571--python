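import numpy as np
import pytest

from longconn.io import Connectome
from longconn.simulate import synthetic_parcellation


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)


@pytest.fixture(scope="session")
def parc_scale1():
    return synthetic_parcellation(1)


@pytest.fixture(scope="session")
def parc_scale3():
    return synthetic_parcellation(3)


def make_connectome(w, parc, subject_id="s0", timepoint="control"):
    return Connectome(
        matrix=np.asarray(w, dtype=float),
        parcel_ids=parc.parcel_ids,
        scale=parc.scale,
        subject_id=subject_id,
        timepoint=timepoint,
    )


@pytest.fixture
def triangle():
    """Unit-weight triangle adjacency."""
    w = np.ones((3, 3)) - np.eye(3)
    return w


@pytest.fixture
def star4():
    """Star S4: hub node 0 with three unit-weight leaves."""
    w = np.zeros((4, 4))
    w[0, 1:] = 1.0
    w[1:, 0] = 1.0
    return w
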