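import pytest

from osteotrace import ancestry, haplotree

# Hand-built miniature tree used for worked-by-hand expectations.
# rCRS -> M -> M39 and rCRS -> N -> R -> R32; plus a back-mutation branch.
FIXTURE_TREE_TEXT = """\
rCRS
\tM\tT489C
\t\tM39\tC12361T
\tN\tG8701A
\t\tR\tT16189C
\t\t\tR32\tG9962A A13105G
\t\t\tRv\tC150T A8701G!
"""


@pytest.fixture(scope="session")
def default_tree():
    return haplotree.load_default_tree()


@pytest.fixture(scope="session")
def default_panel():
    return haplotree.load_default_panel()


@pytest.fixture(scope="session")
def default_reference(default_tree):
    return default_tree.reference_alleles()


@pytest.fixture(scope="session")
def region_map():
    return ancestry.default_region_map()


@pytest.fixture()
def fixture_tree():
    return haplotree.parse_haplotree(FIXTURE_TREE_TEXT)
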