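import pytest

from karyoanc.character_extraction import build_character_matrix
from karyoanc.karyotype_assembly import InferenceConfig, karyotype_from_map
from karyoanc.painting_io import load_fixtures
from karyoanc.parsimony import PhyloTree


@pytest.fixture(scope="session")
def fixtures():
    return load_fixtures()


@pytest.fixture(scope="session")
def tree(fixtures):
    return PhyloTree.from_newick(fixtures.tree_newick)


@pytest.fixture(scope="session")
def paper_config(fixtures):
    return InferenceConfig.from_dict(fixtures.paper_config, fixtures.overrides)


@pytest.fixture(scope="session")
def matrix(fixtures):
    """Default character matrix: eight species + AEK outgroup, policy
    'missing', with the configured containment credit."""
    return build_character_matrix(
        fixtures.matrix_maps, policy="missing",
        association_credits=fixtures.paper_config["association_credits"])


@pytest.fixture(scope="session")
def aek_karyotype(fixtures):
    return karyotype_from_map(fixtures.maps["AEK"])


def binary_column(matrix, label):
    """Association multiplicities collapsed to presence/absence, keeping
    missing as missing."""
    ch = matrix.get(label)
    out = {}
    for taxon in matrix.taxa:
        s = matrix.state(ch, taxon)
        if s is None:
            out[taxon] = None
        else:
            hi = s[1] if isinstance(s, tuple) else s
            out[taxon] = 1 if hi >= 1 else 0
    return out
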