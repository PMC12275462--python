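import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from phyloshift import NeutralModel, build_rev, read_newick

settings.register_profile(
    "suite",
    deadline=None,
    derandomize=True,
    max_examples=25,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")

NEWICK4 = "((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05);"
NEWICK10 = (
    "(((A:0.1,B:0.1):0.05,(C:0.1,D:0.1):0.05):0.05,"
    "((E:0.1,F:0.1):0.05,((G:0.1,H:0.1):0.05,(I:0.1,J:0.1):0.05):0.03):0.04);"
)


def make_tree20():
    """A 20-tip ladder with uniform-ish branch lengths."""
    s = "(t0:0.1,t1:0.1)"
    for i in range(2, 20):
        s = f"({s}:0.05,t{i}:0.1)"
    return read_newick(s + ";")


def attach(model: NeutralModel, tree) -> NeutralModel:
    return NeutralModel(model.Q, model.pi, tree)


@pytest.fixture(scope="session")
def tree4():
    return read_newick(NEWICK4)


@pytest.fixture(scope="session")
def tree10():
    return read_newick(NEWICK10)


@pytest.fixture(scope="session")
def tree20():
    return make_tree20()


@pytest.fixture(scope="session")
def jc_model():
    return build_rev(np.ones(6), np.full(4, 0.25))


@pytest.fixture(scope="session")
def rev_model():
    """Transition-biased model with skewed frequencies."""
    return build_rev([1.0, 3.0, 1.0, 1.0, 3.0, 1.0], [0.3, 0.2, 0.2, 0.3])


@pytest.fixture(scope="session")
def model4(rev_model, tree4):
    return attach(rev_model, tree4)


@pytest.fixture(scope="session")
def model10(rev_model, tree10):
    return attach(rev_model, tree10)


@pytest.fixture(scope="session")
def model20(rev_model, tree20):
    return attach(rev_model, tree20)
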