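import dendropy
import numpy as np
import pytest

from cytodisc import parse_newick


@pytest.fixture
def rng():
    return np.random.default_rng(20240520)


def make_triplet(t_internal=None) -> dendropy.Tree:
    """Rooted triplet ((A,B):T,C); with terminal lengths 1 and internal T."""
    if t_internal is None:
        return parse_newick("((A,B),C);")
    return parse_newick(f"((A:1,B:1):{t_internal},C:1);")


def make_quartet(t_internal: float) -> dendropy.Tree:
    """Balanced quartet ((A,B):T,(C,D):T); internal CU length T."""
    return parse_newick(f"((A:1,B:1):{t_internal},(C:1,D:1):{t_internal});")
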