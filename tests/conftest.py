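"""Shared fixtures: random feasible linkages and small reference trees."""

import numpy as np
import pytest

from linkage_evo import FourBarLinkage, Phylogeny, assembly_range
from linkage_evo.errors import NonClosableLinkage


def random_feasible_linkage(rng, min_range=1.0):
    """Draw a random linkage whose assembly range spans > min_range degrees."""
    while True:
        lengths = rng.uniform(0.3, 3.0, size=4)
        try:
            link = FourBarLinkage(*lengths)
            lo, hi = assembly_range(link)
        except NonClosableLinkage:
            continue
        if hi - lo > min_range:
            return link


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20180809)


@pytest.fixture(scope="session")
def three_taxon_tree():
    return Phylogeny.from_newick("((A:1,B:1):1,C:2);")


@pytest.fixture(scope="session")
def parallelogram():
    # fixed=2, input=1, output=1, coupler=2
    return FourBarLinkage(2.0, 1.0, 1.0, 2.0)
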