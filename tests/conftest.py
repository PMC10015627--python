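import warnings

import pytest

from phyloregime.simulate import (
    elegans_like_painting,
    elegans_like_tree,
    make_study_fixture,
)
from phyloregime.tree import read_newick

warnings.filterwarnings("ignore", message=".*lower bound.*")


@pytest.fixture(scope="session")
def elegans_tree():
    return elegans_like_tree()


@pytest.fixture(scope="session")
def elegans_painting(elegans_tree):
    return elegans_like_painting(elegans_tree)


@pytest.fixture(scope="session")
def study_fixture():
    return make_study_fixture(0)


@pytest.fixture()
def two_tip_tree():
    return read_newick("(A:1.0,B:1.0);")
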