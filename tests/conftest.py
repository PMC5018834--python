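import numpy as np
import pytest

from h2agc import Peptide, digest
from h2agc.data import mouse_h2a_records, reference_h2a

G37K74 = "GNYSERVGAGAPVYLAAVLEYLTAEILELAGNAARDNK"


@pytest.fixture(scope="session")
def ref_h2a() -> str:
    return reference_h2a()


@pytest.fixture(scope="session")
def h2a_fixture_records():
    return mouse_h2a_records()


@pytest.fixture(scope="session")
def g37k74(ref_h2a) -> Peptide:
    pep = next(p for p in digest(ref_h2a) if p.start_pos == 37)
    assert pep.sequence == G37K74
    return pep


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20160912)


def random_peptide(rng: np.random.Generator, min_len: int = 2, max_len: int = 30) -> Peptide:
    alphabet = "ACDEFGHIKLMNPQRSTVWY"
    n = int(rng.integers(min_len, max_len + 1))
    seq = "".join(alphabet[i] for i in rng.integers(0, 20, n))
    return Peptide(seq, 1, n)
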