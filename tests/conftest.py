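import numpy as np
import pytest

from rotpos.energy import build_nucleosome_template
from rotpos.params import default_table


@pytest.fixture(scope="session")
def params():
    return default_table()


@pytest.fixture(scope="session")
def template101():
    return build_nucleosome_template(101, 10.0, 4.5)


@pytest.fixture()
def rng():
    return np.random.default_rng(20240901)


def random_sequence(rng, n, p=(0.25, 0.25, 0.25, 0.25)):
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


@pytest.fixture()
def make_seq(rng):
    return lambda n: random_sequence(rng, n)
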