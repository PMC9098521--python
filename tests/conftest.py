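import json

import pytest

from litnet.corpus import parse_pubtator
from litnet.fixtures import FixtureSpec, make_all
from litnet.ontology import load_mesh, load_taxonomy_dump


@pytest.fixture(scope="session")
def artifacts():
    """Default seeded fixture bundle (seed 7)."""
    return make_all(FixtureSpec())


@pytest.fixture(scope="session")
def groundtruth(artifacts):
    return json.loads(artifacts["groundtruth.json"])


@pytest.fixture(scope="session")
def corpus(artifacts):
    return parse_pubtator(artifacts["corpus.pubtator"], strict_offsets=True)


@pytest.fixture(scope="session")
def taxonomy(artifacts):
    return load_taxonomy_dump(artifacts["nodes.dmp"], artifacts["names.dmp"])


@pytest.fixture(scope="session")
def mesh(artifacts):
    return load_mesh(artifacts["mesh.tsv"], "tsv")


@pytest.fixture(scope="session")
def big_artifacts():
    """Larger corpus for the co-occurrence oracle: 200 docs, 50 entities
    (20 species + 30 MeSH descriptors)."""
    return make_all(FixtureSpec(seed=7, n_docs=200, n_mesh_descriptors=30,
                                entities_per_doc=(2, 6)))


@pytest.fixture(scope="session")
def big_corpus(big_artifacts):
    return parse_pubtator(big_artifacts["corpus.pubtator"], strict_offsets=True)
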