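"""Ontology graphs: concepts, is-a hierarchy, and lateral relationships.

A biomedical ontology hierarchy is modelled as a rooted directed acyclic
graph of concepts linked by *is-a* (subsumption) edges, where each concept
may additionally carry *lateral* (non-hierarchical) relationship assertions
such as SNOMED CT attribute relationships or NCIt roles.  Lateral targets
may lie in other hierarchies and are kept as opaque identifiers.

:class:`OntologyGraph` is the single in-memory container consumed by the
taxonomy-derivation and audit machinery.  It wraps a :mod:`networkx`
DiGraph whose edges point child → parent.
"""

from __future__ import annotations

import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import networkx as nx
import pandas as pd

__all__ = [
    "Concept",
    "IsAEdge",
    "LateralAssertion",
    "OntologyGraph",
    "OntologyError",
    "CycleError",
    "load_ontology",
    "read_obo",
    "effective_rel_types",
    "descendants",
    "ancestors",
    "complexity_ratio",
]


class OntologyError(ValueError):
    """Raised when input tables violate the ontology-graph invariants."""


class CycleError(OntologyError):
    """Raised when the is-a edges contain a cycle.

    The offending cycle is available as the ``cycle`` attribute
    (a list of concept ids, first repeated last).
    """

    def __init__(self, cycle: list[str]):
        self.cycle = list(cycle)
        super().__init__(
            "is-a edges contain a cycle: " + " -> ".join(self.cycle)
        )


@dataclass(frozen=True)
class Concept:
    """A single ontology concept.

    Parameters
    ----------
    id : str
        Unique, non-empty identifier (compared case-sensitively).
    label : str
        Human-readable name.
    asserted_rel_types : frozenset of str
        Distinct lateral relationship-type names asserted on this concept.
        May be empty (the Ø case).
    """

    id: str
    label: str = ""
    asserted_rel_types: frozenset = field(default_factory=frozenset)


@dataclass(frozen=True)
class IsAEdge:
    """A subsumption edge: ``child`` is-a ``parent``."""

    child: str
    parent: str


@dataclass(frozen=True)
class LateralAssertion:
    """A lateral relationship assertion ``source --rel_type--> target``.

    ``target`` is an opaque id and is never validated against the loaded
    concept set: lateral relationships routinely point into other
    hierarchies.
    """

    source: str
    rel_type: str
    target: str


class OntologyGraph:
    """Validated concept hierarchy with lateral relationship assertions.

    Parameters
    ----------
    concepts : iterable of Concept
    isa_edges : iterable of IsAEdge
    assertions : iterable of LateralAssertion
        ``asserted_rel_types`` of each concept is recomputed as the set of
        distinct rel_type values of its assertions.

    Raises
    ------
    OntologyError
        On duplicate or empty concept ids, edges or assertions referencing
        unknown concepts, or self-edges.
    CycleError
        If the is-a edges are not acyclic.
    """

    def __init__(
        self,
        concepts: Iterable[Concept],
        isa_edges: Iterable[IsAEdge] = (),
        assertions: Iterable[LateralAssertion] = (),
    ):
        self._labels: dict[str, str] = {}
        for c in concepts:
            if not c.id:
                raise OntologyError("empty concept id")
            if c.id in self._labels:
                raise OntologyError(f"duplicate concept id: {c.id!r}")
            self._labels[c.id] = c.label
        if not self._labels:
            raise OntologyError("ontology has no concepts")

        self.isa_edges: list[IsAEdge] = []
        seen_edges: set[tuple[str, str]] = set()
        # child -> parent digraph
        g = nx.DiGraph()
        g.add_nodes_from(self._labels)
        for e in isa_edges:
            if e.child == e.parent:
                raise OntologyError(f"self is-a edge on {e.child!r}")
            for cid in (e.child, e.parent):
                if cid not in self._labels:
                    raise OntologyError(f"is-a edge references unknown concept {cid!r}")
            if (e.child, e.parent) in seen_edges:
                continue
            seen_edges.add((e.child, e.parent))
            self.isa_edges.append(e)
            g.add_edge(e.child, e.parent)
        try:
            cyc = nx.find_cycle(g)
        except nx.NetworkXNoCycle:
            pass
        else:
            nodes = [u for u, _ in cyc] + [cyc[-1][1]]
            raise CycleError(nodes)
        self._g = g

        self.assertions: list[LateralAssertion] = []
        rel_sets: dict[str, set[str]] = {cid: set() for cid in self._labels}
        for a in assertions:
            if a.source not in self._labels:
                raise OntologyError(f"assertion source unknown: {a.source!r}")
            if not a.rel_type:
                raise OntologyError(f"empty rel_type on assertion from {a.source!r}")
            self.assertions.append(a)
            rel_sets[a.source].add(a.rel_type)
        self._rel_sets = {cid: frozenset(s) for cid, s in rel_sets.items()}

    # -- basic queries -------------------------------------------------

    @property
    def concept_ids(self) -> list[str]:
        """All concept ids in stable sorted order."""
        return sorted(self._labels)

    def __len__(self) -> int:
        return len(self._labels)

    def __contains__(self, cid: str) -> bool:
        return cid in self._labels

    def label(self, cid: str) -> str:
        return self._labels[cid]

    def concept(self, cid: str) -> Concept:
        return Concept(cid, self._labels[cid], self._rel_sets[cid])

    @property
    def roots(self) -> list[str]:
        """Concept ids with no parents, sorted."""
        return sorted(c for c in self._labels if self._g.out_degree(c) == 0)

    def parents(self, cid: str) -> set[str]:
        self._check(cid)
        return set(self._g.successors(cid))

    def children(self, cid: str) -> set[str]:
        self._check(cid)
        return set(self._g.predecessors(cid))

    def asserted_rel_types(self, cid: str) -> frozenset:
        self._check(cid)
        return self._rel_sets[cid]

    @property
    def observed_rel_types(self) -> set[str]:
        return {a.rel_type for a in self.assertions}

    def _check(self, cid: str) -> None:
        if cid not in self._labels:
            raise KeyError(f"unknown concept id {cid!r}")

    # -- derived structure --------------------------------------------

    def descendants(self, cid: str) -> set[str]:
        """Transitive closure below ``cid`` (excluding ``cid``)."""
        self._check(cid)
        # edges point child -> parent, so descendants are graph ancestors
        return nx.ancestors(self._g, cid)

    def ancestors(self, cid: str) -> set[str]:
        """Transitive closure above ``cid`` (excluding ``cid``)."""
        self._check(cid)
        return nx.descendants(self._g, cid)

    def effective_rel_types(self, mode: str = "asserted") -> dict[str, frozenset]:
        """Effective lateral relationship-type set per concept.

        ``mode='asserted'`` returns the asserted sets unchanged — the right
        choice for inferred (reasoner-materialised) releases where
        inheritance is already explicit.  ``mode='inherited'`` unions each
        concept's asserted set with those of all its ancestors, for raw
        (stated) inputs, since lateral relationships are inherited from
        parent to child.
        """
        if mode == "asserted":
            return dict(self._rel_sets)
        if mode != "inherited":
            raise ValueError(f"mode must be 'asserted' or 'inherited', got {mode!r}")
        eff: dict[str, set[str]] = {}
        # process parents before children: topological order on parent->child
        for cid in reversed(list(nx.topological_sort(self._g))):
            s = set(self._rel_sets[cid])
            for p in self._g.successors(cid):
                s |= eff[p]
            eff[cid] = s
        return {cid: frozenset(s) for cid, s in eff.items()}

    def complexity_ratio(self) -> float:
        """(is-a edges + lateral assertions) / concepts."""
        return complexity_ratio(
            n_isa=len(self.isa_edges),
            n_lateral=len(self.assertions),
            n_concepts=len(self),
        )

    def subgraph_under(self, root: str) -> "OntologyGraph":
        """Extract the sub-hierarchy rooted at ``root``.

        Keeps ``root`` and all its descendants, the is-a edges among them,
        and their lateral assertions (including assertions whose targets
        fall outside the extracted hierarchy — only the type set matters
        downstream).
        """
        self._check(root)
        keep = self.descendants(root) | {root}
        return OntologyGraph(
            [self.concept(c) for c in sorted(keep)],
            [e for e in self.isa_edges if e.child in keep and e.parent in keep],
            [a for a in self.assertions if a.source in keep],
        )

    # -- (de)serialisation --------------------------------------------

    def to_tables(self) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
        """Return (concepts, isa, lateral) DataFrames in the TSV dialect."""
        concepts = pd.DataFrame(
            [(c, self._labels[c]) for c in sorted(self._labels)],
            columns=["id", "label"],
        )
        isa = pd.DataFrame(
            sorted((e.child, e.parent) for e in self.isa_edges),
            columns=["child_id", "parent_id"],
        )
        lateral = pd.DataFrame(
            sorted((a.source, a.rel_type, a.target) for a in self.assertions),
            columns=["source_id", "rel_type", "target_id"],
        )
        return concepts, isa, lateral

    def write_tsv(self, outdir: str | os.PathLike) -> None:
        """Write concepts.tsv / isa.tsv / lateral.tsv under ``outdir``."""
        concepts, isa, lateral = self.to_tables()
        os.makedirs(outdir, exist_ok=True)
        concepts.to_csv(os.path.join(outdir, "concepts.tsv"), sep="\t", index=False)
        isa.to_csv(os.path.join(outdir, "isa.tsv"), sep="\t", index=False)
        lateral.to_csv(os.path.join(outdir, "lateral.tsv"), sep="\t", index=False)


def _read_table(source, columns: tuple[str, ...]) -> pd.DataFrame:
    if isinstance(source, pd.DataFrame):
        df = source
    else:
        df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise OntologyError(f"table missing columns {missing}; has {list(df.columns)}")
    return df


def load_ontology(concepts_table, isa_table, lateral_table=None) -> OntologyGraph:
    """Load an :class:`OntologyGraph` from three tabular sources.

    Each source is a path / file-like object holding a UTF-8 TSV with a
    header row, or an equivalent :class:`pandas.DataFrame`:

    - concepts: ``id``, ``label``
    - is-a edges: ``child_id``, ``parent_id``
    - lateral assertions: ``source_id``, ``rel_type``, ``target_id``
      (optional; omit for a hierarchy without lateral relationships)
    """
    cdf = _read_table(concepts_table, ("id", "label"))
    idf = _read_table(isa_table, ("child_id", "parent_id"))
    concepts = [Concept(r.id, r.label) for r in cdf.itertuples(index=False)]
    edges = [IsAEdge(r.child_id, r.parent_id) for r in idf.itertuples(index=False)]
    assertions: list[LateralAssertion] = []
    if lateral_table is not None:
        ldf = _read_table(lateral_table, ("source_id", "rel_type", "target_id"))
        assertions = [
            LateralAssertion(r.source_id, r.rel_type, r.target_id)
            for r in ldf.itertuples(index=False)
        ]
    return OntologyGraph(concepts, edges, assertions)


def read_obo(source) -> OntologyGraph:
    """Load an OBO flat file as an :class:`OntologyGraph`.

    Maps term ``id`` → concept id, ``name`` → label, ``is_a`` lines →
    is-a edges, and ``relationship: <type> <target>`` lines → lateral
    assertions.  Obsolete terms are skipped by the underlying reader.
    """
    import obonet

    if isinstance(source, str) and "\n" in source:
        source = io.StringIO(source)
    g = obonet.read_obo(source)
    concepts = [Concept(n, g.nodes[n].get("name", "")) for n in g.nodes]
    edges: list[IsAEdge] = []
    assertions: list[LateralAssertion] = []
    known = set(g.nodes)
    for child, parent, key in g.edges(keys=True):
        if key == "is_a":
            if parent in known:
                edges.append(IsAEdge(child, parent))
        else:
            assertions.append(LateralAssertion(child, key, parent))
    return OntologyGraph(concepts, edges, assertions)


def effective_rel_types(g: OntologyGraph, mode: str = "asserted") -> dict[str, frozenset]:
    """Functional alias for :meth:`OntologyGraph.effective_rel_types`."""
    return g.effective_rel_types(mode)


def descendants(g: OntologyGraph, cid: str) -> set[str]:
    """Functional alias for :meth:`OntologyGraph.descendants`."""
    return g.descendants(cid)


def ancestors(g: OntologyGraph, cid: str) -> set[str]:
    """Functional alias for :meth:`OntologyGraph.ancestors`."""
    return g.ancestors(cid)


def complexity_ratio(
    g: OntologyGraph | None = None,
    *,
    n_isa: int | None = None,
    n_lateral: int | None = None,
    n_concepts: int | None = None,
) -> float:
    """Ontology complexity: relationships per concept.

    Defined as (number of is-a edges + number of lateral relationship
    assertions) / number of concepts.  Callable either on a graph or with
    explicit counts, e.g. published release-level totals.
    """
    if g is not None:
        return g.complexity_ratio()
    if n_concepts is None or n_isa is None or n_lateral is None:
        raise ValueError("provide a graph or all three counts")
    if n_concepts <= 0:
        raise ValueError("concept count must be positive")
    return (n_isa + n_lateral) / n_concepts
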