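import numpy as np
import pytest

from famevol import synthetic
from famevol.trees import SpeciesTree


@pytest.fixture(scope="session")
def demo_tree():
    return synthetic.demo_tree()


@pytest.fixture(scope="session")
def five_taxon_tree():
    return SpeciesTree.from_newick(
        "((A:0.08,B:0.08):0.05,((C:0.06,D:0.06):0.04,E:0.1):0.03);"
    )


@pytest.fixture(scope="session")
def ladder_tree():
    # rooted 4-taxon tree whose root-adjacent branches fall in one ratio
    # class; keeps two-ratio branch models identifiable
    return SpeciesTree.from_newick("(((C:0.08,D:0.08):0.06,A:0.1):0.05,B:0.13);")


@pytest.fixture
def rng():
    return np.random.default_rng(0)
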