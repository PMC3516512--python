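import numpy as np
import pytest

from sigflux.core import Compound, Model, Reaction, UNBOUNDED
from sigflux.gpr import parse_gpr


def chain_model(with_gpr: bool = False) -> Model:
    """EX_A (uptake) -> R1: A->B -> DM_B, a minimal flux-carrying chain."""
    m = Model("chain")
    m.add_compound(Compound("A[c]", "A", "c", "metabolite"))
    m.add_compound(Compound("B[c]", "B", "c", "metabolite"))
    m.add_reaction(Reaction("EX_A", {"A[c]": -1.0}, -1.0, 0.0, rclass="exchange"))
    gpr = parse_gpr("g1 or g2") if with_gpr else parse_gpr("")
    m.add_reaction(Reaction("R1", {"A[c]": -1.0, "B[c]": 1.0}, 0.0, UNBOUNDED, gpr))
    m.add_reaction(Reaction("DM_B", {"B[c]": -1.0}, 0.0, UNBOUNDED, rclass="demand"))
    return m


@pytest.fixture
def chain():
    return chain_model()


@pytest.fixture(scope="session")
def minitlr():
    from sigflux.synthetic import mini_tlr
    return mini_tlr()


@pytest.fixture(scope="session")
def minitlr_io():
    from sigflux.synthetic import mini_tlr_io
    return mini_tlr_io()


@pytest.fixture(scope="session")
def expectations():
    from sigflux.synthetic import mini_tlr_expectations
    return mini_tlr_expectations()


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
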