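import numpy as np
import pytest

from splicemap.phylo import parse_newick


@pytest.fixture
def three_taxon_tree():
    """((A:1,B:1):1,C:2); -- ultrametric, depth 2."""
    return parse_newick("((A:1,B:1):1,C:2);")


@pytest.fixture
def four_taxon_tree():
    return parse_newick("((A:1,B:1):1,(C:1,D:1):1);")


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
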