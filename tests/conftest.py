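import pytest

import partax as px


@pytest.fixture(scope="session")
def gene_excerpt():
    """The 12-concept worked-example gene hierarchy."""
    return px.build_gene_excerpt()


@pytest.fixture(scope="session")
def gene_excerpt_pat(gene_excerpt):
    return px.derive_partial_area_taxonomy(gene_excerpt)


@pytest.fixture
def random_graph():
    """Factory for seeded random ontology graphs."""

    def make(seed, n=60, n_rel_types=3, multi_parent_prob=0.25, mutation_prob=0.3):
        cfg = px.GeneratorConfig(n, n_rel_types, multi_parent_prob, mutation_prob, seed)
        return px.generate_ontology(cfg)

    return make
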