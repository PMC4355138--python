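import pytest

from phenosearch import canonical_fixture, compute_ic


@pytest.fixture(scope="session")
def canonical():
    """(graph, corpus) of the hand-checkable 5-term / 4-entity fixture."""
    return canonical_fixture()


@pytest.fixture(scope="session")
def canonical_graph(canonical):
    return canonical[0]


@pytest.fixture(scope="session")
def canonical_corpus(canonical):
    return canonical[1]


@pytest.fixture(scope="session")
def canonical_ic(canonical):
    return compute_ic(canonical[1])


CANONICAL_OBO = """\
format-version: 1.2
ontology: synthetic-phenotype

[Term]
id: XP:0000000
name: root

[Term]
id: XP:0000001
name: A
is_a: XP:0000000 ! root

[Term]
id: XP:0000002
name: B
is_a: XP:0000000 ! root

[Term]
id: XP:0000003
name: C
alt_id: XP:0000093
is_a: XP:0000001 ! A

[Term]
id: XP:0000004
name: D
is_a: XP:0000001 ! A
is_a: XP:0000002 ! B
"""

CANONICAL_ANNOTATIONS_TSV = """\
# synthetic worked-example corpus
entity_id\tentity_type\tspecies\tterm_id
e1\tgene\tsynthetic\tXP:0000003
e2\tgene\tsynthetic\tXP:0000003
e2\tgene\tsynthetic\tXP:0000002
e3\tgene\tsynthetic\tXP:0000004
e4\tgene\tsynthetic\tXP:0000002
"""


@pytest.fixture
def obo_file(tmp_path):
    path = tmp_path / "fixture.obo"
    path.write_text(CANONICAL_OBO)
    return path


@pytest.fixture
def annotations_file(tmp_path):
    path = tmp_path / "annotations.tsv"
    path.write_text(CANONICAL_ANNOTATIONS_TSV)
    return path
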