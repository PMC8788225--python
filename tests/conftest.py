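import numpy as np
import pytest

from evoprofiler.data_model_io import read_tree_string, orthology_from_members


@pytest.fixture
def abc_tree():
    """((A:1,B:1):1,C:2); root age 2, internal node age 1."""
    return read_tree_string("((A:1,B:1):1,C:2);")


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def make_orthology(members, species):
    return orthology_from_members(members, species)


@pytest.fixture
def simple_orthology():
    members = {
        "og1": [("g1", "A"), ("g2", "B")],
        "og2": [("g3", "A"), ("g4", "A"), ("g5", "C")],
    }
    return make_orthology(members, ["A", "B", "C"])
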