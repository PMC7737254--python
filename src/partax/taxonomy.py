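"""Area and partial-area taxonomy derivation.

The partial-area taxonomy is a compact summarization network of a concept
hierarchy.  Concepts are first partitioned into *areas* — maximal groups
sharing exactly the same set of lateral relationship types — and each area
is subdivided into *partial-areas*, one per area root (a member all of
whose parents lie outside the area), containing the root plus every member
reachable from it by an is-a path that stays inside the area.  *Child-of*
links between the summary nodes are induced by the is-a parents of roots.

Concepts in *small* partial-areas (size at most a bound ``b``) are
uncommonly modelled outlier concepts and are the audit targets of the QA
methodology in :mod:`partax.audit`.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd

from .ontology import OntologyGraph, Concept, IsAEdge, LateralAssertion

__all__ = [
    "Area",
    "PartialArea",
    "AreaTaxonomy",
    "PartialAreaTaxonomy",
    "OverlapReport",
    "derive_area_taxonomy",
    "derive_partial_area_taxonomy",
    "derive_subtaxonomy",
    "find_overlapping_concepts",
    "size_distribution",
    "classify_small_large",
    "area_label",
]


def area_label(rel_type_set: frozenset) -> str:
    """Canonical area label: sorted type names joined by ', '; Ø if empty."""
    return ", ".join(sorted(rel_type_set)) if rel_type_set else "Ø"


@dataclass(frozen=True)
class Area:
    """All concepts sharing exactly one set of lateral relationship types."""

    rel_type_set: frozenset
    members: frozenset
    roots: frozenset

    @property
    def label(self) -> str:
        return area_label(self.rel_type_set)

    @property
    def size(self) -> int:
        return len(self.members)


@dataclass(frozen=True)
class PartialArea:
    """A root concept plus its within-area descendants."""

    root: str
    members: frozenset
    area_key: frozenset
    root_label: str = ""

    @property
    def size(self) -> int:
        return len(self.members)

    @property
    def label(self) -> str:
        return f"{self.root_label or self.root} ({self.size})"


@dataclass
class AreaTaxonomy:
    """Areas plus child-of links (pairs of area rel-type-set keys)."""

    areas: dict  # frozenset -> Area
    child_of: set  # {(child_key, parent_key)}

    def area_of(self, cid: str) -> Area:
        for a in self.areas.values():
            if cid in a.members:
                return a
        raise KeyError(cid)

    @property
    def n_concepts(self) -> int:
        return sum(a.size for a in self.areas.values())


@dataclass
class PartialAreaTaxonomy:
    """Partial-areas (keyed by root id) plus child-of links between roots."""

    partial_areas: dict  # root id -> PartialArea
    child_of: set  # {(child_root, parent_root)}
    area_taxonomy: AreaTaxonomy
    mode: str = "asserted"

    @property
    def n_concepts(self) -> int:
        return self.area_taxonomy.n_concepts

    def membership(self) -> dict[str, list[str]]:
        """concept id -> sorted list of containing partial-area roots."""
        m: dict[str, list[str]] = {}
        for root in sorted(self.partial_areas):
            for cid in self.partial_areas[root].members:
                m.setdefault(cid, []).append(root)
        return m

    def sizes_by_concept(self) -> dict[str, int]:
        """concept id -> partial-area size (minimum if overlapping)."""
        return {
            cid: min(self.partial_areas[r].size for r in roots)
            for cid, roots in self.membership().items()
        }

    # -- export --------------------------------------------------------

    def to_node_link_tables(self) -> tuple[pd.DataFrame, pd.DataFrame]:
        """(nodes, links) DataFrames covering areas and partial-areas.

        Ordering is (size desc, label asc) within each kind for
        reproducible, byte-identical reports.
        """
        at = self.area_taxonomy
        akey = {k: "area:" + area_label(k) for k in at.areas}
        rows = [
            (akey[k], "area", a.label, a.size, area_label(k))
            for k, a in at.areas.items()
        ]
        rows.sort(key=lambda r: (-r[3], r[2]))
        prows = [
            ("pa:" + root, "partial_area", pa.label, pa.size, area_label(pa.area_key))
            for root, pa in self.partial_areas.items()
        ]
        prows.sort(key=lambda r: (-r[3], r[2]))
        nodes = pd.DataFrame(
            rows + prows, columns=["node_id", "kind", "label", "size", "rel_types"]
        )
        links = sorted(
            [(akey[c], akey[p]) for c, p in at.child_of]
            + [("pa:" + c, "pa:" + p) for c, p in self.child_of]
        )
        links_df = pd.DataFrame(links, columns=["child_node_id", "parent_node_id"])
        return nodes, links_df

    def write_tsv(self, outdir: str | os.PathLike) -> None:
        nodes, links = self.to_node_link_tables()
        os.makedirs(outdir, exist_ok=True)
        nodes.to_csv(os.path.join(outdir, "nodes.tsv"), sep="\t", index=False)
        links.to_csv(os.path.join(outdir, "links.tsv"), sep="\t", index=False)

    def to_dot(self) -> str:
        """Graphviz DOT rendering: partial-areas clustered by area."""
        at = self.area_taxonomy
        lines = ["digraph partial_area_taxonomy {", "  rankdir=BT;"]
        for i, k in enumerate(sorted(at.areas, key=area_label)):
            lines.append(f'  subgraph cluster_{i} {{ label="{area_label(k)}";')
            for root, pa in sorted(self.partial_areas.items()):
                if pa.area_key == k:
                    lines.append(f'    "{root}" [label="{pa.label}"];')
            lines.append("  }")
        for c, p in sorted(self.child_of):
            lines.append(f'  "{c}" -> "{p}";')
        lines.append("}")
        return "\n".join(lines)


@dataclass
class OverlapReport:
    """Concepts belonging to two or more partial-areas."""

    overlapping: set
    containment: dict  # concept id -> sorted list of partial-area roots


def _effective(g: OntologyGraph, mode: str) -> dict[str, frozenset]:
    return g.effective_rel_types(mode)


def derive_area_taxonomy(g: OntologyGraph, mode: str = "asserted") -> AreaTaxonomy:
    """Partition concepts into areas and derive area child-of links.

    An area groups all concepts whose effective lateral relationship-type
    set is exactly equal; the Ø area exists iff some concept has an empty
    set.  Area A is child-of area B iff some root of A (a member whose
    parents all lie outside A) has a parent in B.
    """
    eff = _effective(g, mode)
    buckets: dict[frozenset, set[str]] = {}
    for cid, s in eff.items():
        buckets.setdefault(s, set()).add(cid)

    areas: dict[frozenset, Area] = {}
    child_of: set[tuple[frozenset, frozenset]] = set()
    for key, members in buckets.items():
        roots = {
            c for c in members if not (g.parents(c) & members)
        }
        areas[key] = Area(key, frozenset(members), frozenset(roots))
    for key, area in areas.items():
        for r in area.roots:
            for p in g.parents(r):
                child_of.add((key, eff[p]))
    return AreaTaxonomy(areas, child_of)


def derive_partial_area_taxonomy(
    g: OntologyGraph, mode: str = "asserted", membership: str = "path"
) -> PartialAreaTaxonomy:
    """Derive the partial-area taxonomy of ``g``.

    For each area and each of its roots ``r``, the partial-area of ``r``
    contains ``r`` plus, under ``membership='path'`` (default), every area
    member reachable from ``r`` by an is-a path lying entirely inside the
    area.  ``membership='descendant'`` instead admits every area member
    that is any is-a descendant of ``r`` (paths may leave the area); this
    looser reading is exposed as a switch because the one-line definition
    "a root and all its descendant concepts in the same area" admits both.

    Partial-area A is child-of partial-area B iff A's root has an is-a
    parent belonging to B.
    """
    if membership not in ("path", "descendant"):
        raise ValueError("membership must be 'path' or 'descendant'")
    at = derive_area_taxonomy(g, mode)
    pas: dict[str, PartialArea] = {}
    for key, area in at.areas.items():
        for r in sorted(area.roots):
            if membership == "path":
                # BFS over children staying inside the area
                members = {r}
                stack = [r]
                while stack:
                    cur = stack.pop()
                    for ch in g.children(cur):
                        if ch in area.members and ch not in members:
                            members.add(ch)
                            stack.append(ch)
            else:
                members = (g.descendants(r) & area.members) | {r}
            pas[r] = PartialArea(r, frozenset(members), key, g.label(r))

    # child-of links: root's parents looked up in every containing partial-area
    containing: dict[str, set[str]] = {}
    for root, pa in pas.items():
        for cid in pa.members:
            containing.setdefault(cid, set()).add(root)
    child_of: set[tuple[str, str]] = set()
    for root in pas:
        for p in g.parents(root):
            for parent_root in containing.get(p, ()):
                child_of.add((root, parent_root))
    return PartialAreaTaxonomy(pas, child_of, at, mode)


def derive_subtaxonomy(
    g: OntologyGraph,
    rel_subset: Iterable[str],
    mode: str = "asserted",
    membership: str = "path",
) -> PartialAreaTaxonomy:
    """Partial-area taxonomy after restricting relationship types.

    Equivalent to deriving on a copy of ``g`` whose effective rel-type
    sets are intersected with ``rel_subset``.  Restricting to a subset
    coarsens the summary: concepts distinguished only by the discarded
    types merge into the partial-areas of their ancestors, shrinking the
    number of small partial-areas.
    """
    import warnings

    rel_subset = frozenset(rel_subset)
    extra = rel_subset - g.observed_rel_types
    if extra:
        warnings.warn(
            f"rel_subset contains unobserved relationship types: {sorted(extra)}",
            stacklevel=2,
        )
    restricted = OntologyGraph(
        [Concept(c, g.label(c)) for c in g.concept_ids],
        list(g.isa_edges),
        [a for a in g.assertions if a.rel_type in rel_subset],
    )
    if mode == "asserted":
        return derive_partial_area_taxonomy(restricted, "asserted", membership)
    # inherited mode: intersect *after* closure, matching the definition
    eff = g.effective_rel_types("inherited")
    synthetic = [
        LateralAssertion(c, t, "_")
        for c in g.concept_ids
        for t in sorted(eff[c] & rel_subset)
    ]
    restricted = OntologyGraph(
        [Concept(c, g.label(c)) for c in g.concept_ids],
        list(g.isa_edges),
        synthetic,
    )
    return derive_partial_area_taxonomy(restricted, "asserted", membership)


def find_overlapping_concepts(pat: PartialAreaTaxonomy) -> OverlapReport:
    """Concepts that belong to two or more partial-areas.

    Overlap requires multiple parents: in a tree-shaped hierarchy the
    report is always empty.
    """
    membership = pat.membership()
    containment = {c: roots for c, roots in membership.items() if len(roots) >= 2}
    return OverlapReport(set(containment), containment)


def size_distribution(
    pat: PartialAreaTaxonomy,
    exclude_overlapping: bool = False,
    bound: int | None = None,
) -> pd.DataFrame:
    """Per-size counts of partial-areas and concepts.

    Returns one row per observed size with columns ``size``,
    ``n_partial_areas``, ``n_concepts`` (sum of member counts, each
    membership counted) and ``n_concepts_eligible`` (distinct
    non-overlapping members); when ``bound`` is given, sizes above it are
    aggregated into a single ``>bound`` row appended after the per-size
    rows, followed by a ``Total`` row.

    With ``exclude_overlapping=True`` the ``n_concepts`` column also drops
    overlapping members, matching a sampling frame that excludes them.
    """
    overlapping = find_overlapping_concepts(pat).overlapping
    per_size: dict[int, list[int]] = {}
    for pa in pat.partial_areas.values():
        row = per_size.setdefault(pa.size, [0, 0, 0])
        row[0] += 1
        eligible = len(pa.members - overlapping)
        row[1] += eligible if exclude_overlapping else pa.size
        row[2] += eligible
    rows = []
    agg = [0, 0, 0, 0]  # count rows for the >bound bucket
    for size in sorted(per_size):
        n_pa, n_c, n_el = per_size[size]
        if bound is not None and size > bound:
            agg[0] += n_pa
            agg[1] += n_c
            agg[2] += n_el
        else:
            rows.append((str(size), n_pa, n_c, n_el))
    if bound is not None:
        rows.append((f">{bound}", agg[0], agg[1], agg[2]))
    total = (
        "Total",
        sum(r[1] for r in rows),
        sum(r[2] for r in rows),
        sum(r[3] for r in rows),
    )
    return pd.DataFrame(
        rows + [total],
        columns=["size", "n_partial_areas", "n_concepts", "n_concepts_eligible"],
    )


def classify_small_large(
    pat: PartialAreaTaxonomy, b: int
) -> tuple[list[PartialArea], list[PartialArea]]:
    """Partition partial-areas into (small: size ≤ b, large: size > b)."""
    if b < 1:
        raise ValueError("bound b must be >= 1")
    small = [pa for pa in pat.partial_areas.values() if pa.size <= b]
    large = [pa for pa in pat.partial_areas.values() if pa.size > b]
    key = lambda pa: (-pa.size, pa.label)
    return sorted(small, key=key), sorted(large, key=key)
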