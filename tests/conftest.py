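import pytest

from polyconflict.trees import parse_newick


@pytest.fixture
def quartet_species():
    """Balanced rooted 4-taxon species tree, one effective internal branch of
    1 CU separating ab from cd (the cd stem has length 0 so c and d cannot
    coalesce before the root)."""
    return parse_newick("((a:1,b:1):1,(c:1,d:1):0);")


@pytest.fixture
def caterpillar6():
    """Six-taxon caterpillar species tree with 0.5-CU branches."""
    return parse_newick(
        "(((((s1:0.5,s2:0.5):0.5,s3:0.5):0.5,s4:0.5):0.5,s5:0.5):0.5,s6:0.5);"
    )


@pytest.fixture
def dstat_species():
    """Asymmetric (((P1,P2),P3),O) species tree in coalescent units."""
    return parse_newick("(((P1:1,P2:1):1,P3:2):1,O:3);")
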