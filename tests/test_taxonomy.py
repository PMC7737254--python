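"""Area / partial-area derivation against brute-force oracles and the
worked 12-concept example."""

import pytest

import partax as px
from partax.ontology import Concept, IsAEdge, LateralAssertion, OntologyGraph
from partax.taxonomy import area_label

from oracles import areas_bruteforce, partial_area_members_bruteforce

GFIO = "Gene Found In Organism"
GPRIP = "Gene Plays Role In Process"


class TestAreaTaxonomy:
    def test_gene_excerpt_areas(self, gene_excerpt):
        at = px.derive_area_taxonomy(gene_excerpt)
        by_label = {a.label: a for a in at.areas.values()}
        assert set(by_label) == {"Ø", GFIO, GPRIP, f"{GFIO}, {GPRIP}"}
        assert by_label[GFIO].size == 2
        assert by_label[GFIO].roots == {"MicroRNA Gene"}
        # the one-type areas are child-of the root area Ø
        assert (frozenset([GFIO]), frozenset()) in at.child_of
        assert (frozenset([GPRIP]), frozenset()) in at.child_of

    def test_no_lateral_assertions_gives_single_null_area(self):
        g = OntologyGraph(
            [Concept(c) for c in "ABC"], [IsAEdge("B", "A"), IsAEdge("C", "B")]
        )
        at = px.derive_area_taxonomy(g)
        assert list(at.areas) == [frozenset()]
        assert at.areas[frozenset()].size == 3
        assert at.child_of == set()

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_bruteforce_bucketing_oracle(self, random_graph, seed):
        g = random_graph(seed, n=100)
        at = px.derive_area_taxonomy(g)
        buckets, roots, links = areas_bruteforce(g)
        assert {k: set(a.members) for k, a in at.areas.items()} == buckets
        assert {k: set(a.roots) for k, a in at.areas.items()} == roots
        assert at.child_of == links

    @pytest.mark.parametrize("seed", range(6))
    def test_areas_partition_concepts(self, random_graph, seed):
        g = random_graph(seed, n=80)
        at = px.derive_area_taxonomy(g)
        assert at.n_concepts == len(g)
        seen = set()
        for a in at.areas.values():
            assert not (seen & a.members)
            seen |= a.members
        assert seen == set(g.concept_ids)


class TestPartialAreaTaxonomy:
    def test_gene_excerpt_partial_areas(self, gene_excerpt_pat):
        pas = gene_excerpt_pat.partial_areas
        labels = {pa.label for pa in pas.values()}
        assert labels == {
            "Gene (2)", "MicroRNA Gene (2)", "Antigen Gene (4)",
            "GAGE6 wt Allele (1)", "CAGE1 wt Allele (3)",
        }
        assert ("GAGE6 wt Allele", "Antigen Gene") in gene_excerpt_pat.child_of
        # Gene (2) is the taxonomy root: no outgoing child-of link
        assert not any(c == "Gene" for c, _ in gene_excerpt_pat.child_of)

    def test_single_root_area_is_one_partial_area(self):
        g = OntologyGraph(
            [Concept(c) for c in "ABC"],
            [IsAEdge("B", "A"), IsAEdge("C", "B")],
            [LateralAssertion(c, "T", "x") for c in "ABC"],
        )
        pat = px.derive_partial_area_taxonomy(g)
        assert set(pat.partial_areas) == {"A"}
        assert pat.partial_areas["A"].members == {"A", "B", "C"}

    @pytest.mark.parametrize("seed", range(6))
    def test_members_match_reachability_oracle(self, random_graph, seed):
        g = random_graph(seed, n=100)
        pat = px.derive_partial_area_taxonomy(g)
        expected = partial_area_members_bruteforce(g)
        assert {r: set(pa.members) for r, pa in pat.partial_areas.items()} == expected

    @pytest.mark.parametrize("seed", range(6))
    def test_union_of_partial_areas_covers_each_area(self, random_graph, seed):
        g = random_graph(seed, n=80)
        pat = px.derive_partial_area_taxonomy(g)
        for key, area in pat.area_taxonomy.areas.items():
            union = set()
            total = 0
            for pa in pat.partial_areas.values():
                if pa.area_key == key:
                    union |= pa.members
                    total += pa.size
            assert union == set(area.members)
            assert total >= area.size

    @pytest.mark.parametrize("seed", range(4))
    def test_child_of_links_are_acyclic(self, random_graph, seed):
        import networkx as nx

        g = random_graph(seed, n=80)
        pat = px.derive_partial_area_taxonomy(g)
        dg = nx.DiGraph(pat.child_of)
        assert nx.is_directed_acyclic_graph(dg)
        at = nx.DiGraph(
            (area_label(c), area_label(p)) for c, p in pat.area_taxonomy.child_of
        )
        assert nx.is_directed_acyclic_graph(at)

    def test_taxonomy_root_contains_hierarchy_root(self, gene_excerpt, gene_excerpt_pat):
        roots_with_no_parent_link = set(gene_excerpt_pat.partial_areas) - {
            c for c, _ in gene_excerpt_pat.child_of
        }
        members = set()
        for r in roots_with_no_parent_link:
            members |= gene_excerpt_pat.partial_areas[r].members
        assert set(gene_excerpt.roots) <= members

    def test_derivation_is_deterministic(self, gene_excerpt):
        a = px.derive_partial_area_taxonomy(gene_excerpt).to_node_link_tables()
        b = px.derive_partial_area_taxonomy(gene_excerpt).to_node_link_tables()
        assert a[0].equals(b[0]) and a[1].equals(b[1])


class TestOverlap:
    def _overlap_graph(self):
        # area T has roots R1, R2 and member M descending from both in-area
        return OntologyGraph(
            [Concept(c) for c in ("Top", "R1", "R2", "M")],
            [IsAEdge("R1", "Top"), IsAEdge("R2", "Top"),
             IsAEdge("M", "R1"), IsAEdge("M", "R2")],
            [LateralAssertion(c, "T", "x") for c in ("R1", "R2", "M")],
        )

    def test_member_of_two_partial_areas_reported(self):
        pat = px.derive_partial_area_taxonomy(self._overlap_graph())
        rep = px.find_overlapping_concepts(pat)
        assert rep.overlapping == {"M"}
        assert rep.containment["M"] == ["R1", "R2"]

    def test_tree_has_no_overlap(self, random_graph):
        g = random_graph(3, n=60, multi_parent_prob=0.0)
        rep = px.find_overlapping_concepts(px.derive_partial_area_taxonomy(g))
        assert rep.overlapping == set()

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_membership_count_oracle(self, random_graph, seed):
        g = random_graph(seed, n=80, multi_parent_prob=0.4)
        pat = px.derive_partial_area_taxonomy(g)
        members = partial_area_members_bruteforce(g)
        counts = {}
        for r, mem in members.items():
            for c in mem:
                counts[c] = counts.get(c, 0) + 1
        expected = {c for c, n in counts.items() if n >= 2}
        assert px.find_overlapping_concepts(pat).overlapping == expected


class TestSizeDistribution:
    def test_gene_excerpt_sizes(self, gene_excerpt_pat):
        df = px.size_distribution(gene_excerpt_pat)
        rows = {r.size: (r.n_partial_areas, r.n_concepts) for r in df.itertuples()}
        assert rows["1"] == (1, 1)
        assert rows["2"] == (2, 4)
        assert rows["3"] == (1, 3)
        assert rows["4"] == (1, 4)

    def test_single_partial_area(self):
        g = OntologyGraph(
            [Concept(c) for c in "ABCD"],
            [IsAEdge(c, "A") for c in "BCD"],
        )
        df = px.size_distribution(px.derive_partial_area_taxonomy(g))
        assert df.iloc[0].tolist() == ["4", 1, 4, 4]

    def test_totals_row_conserves_counts(self, random_graph):
        g = random_graph(5, n=80)
        df = px.size_distribution(px.derive_partial_area_taxonomy(g), bound=5)
        body = df.iloc[:-1]
        total = df.iloc[-1]
        assert total["n_partial_areas"] == body["n_partial_areas"].sum()
        assert total["n_concepts"] == body["n_concepts"].sum()


class TestSubtaxonomy:
    def test_full_type_set_is_identity(self, gene_excerpt, gene_excerpt_pat):
        pat2 = px.derive_subtaxonomy(gene_excerpt, gene_excerpt.observed_rel_types)
        assert {r: pa.members for r, pa in pat2.partial_areas.items()} == {
            r: pa.members for r, pa in gene_excerpt_pat.partial_areas.items()
        }
        assert pat2.child_of == gene_excerpt_pat.child_of

    def test_restriction_merges_two_type_concept_into_ancestor_partial_area(self, gene_excerpt):
        # GAGE6 wt Allele sits alone with {GFIO, GPRIP}; restricted to
        # {GPRIP} it merges into the partial-area rooted at its ancestor
        sub = px.derive_subtaxonomy(gene_excerpt, [GPRIP])
        antigen = sub.partial_areas["Antigen Gene"]
        assert "GAGE6 wt Allele" in antigen.members
        assert "GAGE6 wt Allele" not in sub.partial_areas
        assert antigen.size == 8

    @pytest.mark.parametrize("seed", range(4))
    def test_equals_full_derivation_on_restricted_input(self, random_graph, seed):
        import numpy as np

        g = random_graph(seed, n=70)
        rng = np.random.default_rng(seed)
        types = sorted(g.observed_rel_types)
        subset = {t for t in types if rng.random() < 0.5}
        pat = px.derive_subtaxonomy(g, subset)
        g2 = OntologyGraph(
            [g.concept(c) for c in g.concept_ids],
            list(g.isa_edges),
            [a for a in g.assertions if a.rel_type in subset],
        )
        expected = px.derive_partial_area_taxonomy(g2)
        assert {r: pa.members for r, pa in pat.partial_areas.items()} == {
            r: pa.members for r, pa in expected.partial_areas.items()
        }

    def test_unobserved_type_warns(self, gene_excerpt):
        with pytest.warns(UserWarning, match="unobserved"):
            px.derive_subtaxonomy(gene_excerpt, [GPRIP, "Not A Type"])


class TestClassifySmallLarge:
    def test_all_small_at_generous_bound(self, gene_excerpt_pat):
        small, large = px.classify_small_large(gene_excerpt_pat, 10)
        assert len(small) == 5 and large == []

    def test_bound_just_below_max_isolates_largest(self, gene_excerpt_pat):
        small, large = px.classify_small_large(gene_excerpt_pat, 3)
        assert [pa.label for pa in large] == ["Antigen Gene (4)"]
        assert len(small) == 4

    def test_invalid_bound_rejected(self, gene_excerpt_pat):
        with pytest.raises(ValueError):
            px.classify_small_large(gene_excerpt_pat, 0)


class TestCorrectionMergesOutliers:
    def test_reparenting_moves_concept_out_of_singleton_partial_area(self):
        # A concept with two parents in different partial-areas forms a
        # singleton partial-area; re-pointing the odd parent into the
        # sibling subtree merges it into the larger partial-area.
        concepts = [Concept(c) for c in (
            "Specimen", "Tissue sample", "Soft tissue sample", "Tendon sample",
            "Biopsy sample", "Tendon biopsy sample",
        )]
        lateral = [
            LateralAssertion(c, "Specimen source topography", "x")
            for c in ("Tissue sample", "Soft tissue sample", "Tendon sample",
                      "Tendon biopsy sample")
        ] + [
            LateralAssertion(c, "Specimen procedure", "y")
            for c in ("Biopsy sample", "Tendon biopsy sample")
        ]
        before = OntologyGraph(
            concepts,
            [IsAEdge("Tissue sample", "Specimen"),
             IsAEdge("Soft tissue sample", "Tissue sample"),
             IsAEdge("Tendon sample", "Soft tissue sample"),
             IsAEdge("Biopsy sample", "Tissue sample"),
             IsAEdge("Tendon biopsy sample", "Tendon sample"),
             IsAEdge("Tendon biopsy sample", "Biopsy sample")],
            lateral,
        )
        pat = px.derive_partial_area_taxonomy(before)
        assert pat.partial_areas["Tendon biopsy sample"].size == 1

        lateral_fixed = [a for a in lateral if a.source != "Tendon biopsy sample"] + [
            LateralAssertion("Tendon biopsy sample", "Specimen source topography", "x")
        ]
        after = OntologyGraph(
            concepts,
            [IsAEdge("Tissue sample", "Specimen"),
             IsAEdge("Soft tissue sample", "Tissue sample"),
             IsAEdge("Tendon sample", "Soft tissue sample"),
             IsAEdge("Biopsy sample", "Tissue sample"),
             IsAEdge("Tendon biopsy sample", "Tendon sample"),
             IsAEdge("Tendon biopsy sample", "Soft tissue sample")],
            lateral_fixed,
        )
        pat2 = px.derive_partial_area_taxonomy(after)
        assert "Tendon biopsy sample" not in pat2.partial_areas
        containing = [
            pa for pa in pat2.partial_areas.values()
            if "Tendon biopsy sample" in pa.members
        ]
        assert containing and all(pa.size > 1 for pa in containing)


class TestExport:
    def test_node_link_tables_written_sorted(self, gene_excerpt_pat, tmp_path):
        gene_excerpt_pat.write_tsv(tmp_path)
        import pandas as pd

        nodes = pd.read_csv(tmp_path / "nodes.tsv", sep="\t")
        links = pd.read_csv(tmp_path / "links.tsv", sep="\t")
        pa = nodes[nodes["kind"] == "partial_area"]
        assert list(pa["size"]) == sorted(pa["size"], reverse=True)
        assert len(links) == len(gene_excerpt_pat.child_of) + len(gene_excerpt_pat.area_taxonomy.child_of)

    def test_dot_export_mentions_every_partial_area(self, gene_excerpt_pat):
        dot = gene_excerpt_pat.to_dot()
        for pa in gene_excerpt_pat.partial_areas.values():
            assert pa.label in dot
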