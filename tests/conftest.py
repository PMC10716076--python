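import numpy as np
import pytest

from craniomorph.landmark_sets import default_set
from craniomorph.io import SpecimenRecord
from craniomorph.synthetic import make_template_skull


@pytest.fixture(scope="session")
def neuro_spec():
    return default_set("neurocranial")


@pytest.fixture(scope="session")
def cf_spec():
    return default_set("craniofacial")


@pytest.fixture(scope="session")
def neuro_template(neuro_spec):
    return make_template_skull(neuro_spec)


@pytest.fixture(scope="session")
def cf_template(cf_spec):
    return make_template_skull(cf_spec)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def record_from(coords, present=None, specimen_id="spec", site="", sex="U"):
    coords = np.asarray(coords, dtype=float)
    if present is None:
        present = np.ones(len(coords), dtype=bool)
    return SpecimenRecord(specimen_id, coords, np.asarray(present, bool), site, sex)


@pytest.fixture
def make_record():
    return record_from


def random_rotation(rng):
    A = rng.standard_normal((3, 3))
    Q, R = np.linalg.qr(A)
    Q *= np.sign(np.diag(R))
    if np.linalg.det(Q) < 0:
        Q[:, 2] = -Q[:, 2]
    return Q


@pytest.fixture
def rot():
    return random_rotation
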