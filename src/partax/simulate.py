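"""Synthetic ontologies, planted modelling errors, and simulated audits.

Everything here is a pure function of its seed, so studies replay
byte-identically.  The generator grows a rooted concept DAG by
preferential attachment with occasional extra parents, and inherits each
child's lateral relationship-type set from its parents with occasional
additions — mimicking an inferred (reasoner-materialised) release, where a
concept's asserted types always include its parents' types.  Errors are
planted per concept at stratum-specific rates (higher in small
partial-areas), and a configurable noisy auditor stands in for the human
domain expert.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .ontology import Concept, IsAEdge, LateralAssertion, OntologyGraph
from .taxonomy import PartialAreaTaxonomy, derive_partial_area_taxonomy
from .audit import (
    AuditRecord,
    StudyConfig,
    allocate_proportional,
    build_frame,
    contingency_at_threshold,
    draw_sample,
    fisher_exact_two_tailed,
    size_error_table,
)

__all__ = [
    "GeneratorConfig",
    "PlantedErrorModel",
    "AuditorModel",
    "generate_ontology",
    "build_gene_excerpt",
    "plant_errors",
    "simulate_audit",
    "power_experiment",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs of the random ontology generator.

    ``multi_parent_prob`` is the chance a new concept attaches to a second
    parent (making overlapping concepts possible); ``mutation_prob`` the
    chance its relationship-type set gains a type its parents lack, which
    is what spawns new areas.
    """

    n_concepts: int = 1500
    n_rel_types: int = 4
    multi_parent_prob: float = 0.15
    mutation_prob: float = 0.15
    seed: int = 0

    def __post_init__(self):
        if self.n_concepts < 1:
            raise ValueError("n_concepts must be >= 1")
        for p in (self.multi_parent_prob, self.mutation_prob):
            if not (0.0 <= p <= 1.0):
                raise ValueError("probabilities must be in [0, 1]")


@dataclass(frozen=True)
class PlantedErrorModel:
    """Ground-truth error rates by stratum.

    Defaults are the stratum error rates observed in a hierarchy-scale
    audit of specimen concepts: 22.4% in small partial-areas versus 5.9%
    in large ones, split at bound 9.
    """

    small_rate: float = 0.224
    large_rate: float = 0.059
    bound: int = 9
    seed: int = 0

    def __post_init__(self):
        for r in (self.small_rate, self.large_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")


@dataclass(frozen=True)
class AuditorModel:
    """Imperfect reviewer: flags a planted error with probability
    ``sensitivity`` and a clean concept with probability ``false_positive_rate``."""

    sensitivity: float = 1.0
    false_positive_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        for r in (self.sensitivity, self.false_positive_rate):
            if not (0.0 <= r <= 1.0):
                raise ValueError("rates must be in [0, 1]")


def generate_ontology(cfg: GeneratorConfig) -> OntologyGraph:
    """Grow a random rooted concept DAG with inherited relationship types.

    Concept ``C0000`` is the root with an empty type set.  Each further
    concept attaches to an existing concept chosen preferentially (weight
    1 + current child count), optionally to a second uniform-random
    parent, and starts from the union of its parents' type sets; with
    probability ``mutation_prob`` it gains one extra type.  Inheritance
    from parents keeps asserted sets consistent with an inferred release,
    so asserted and inherited derivation modes agree on these graphs.
    """
    rng = np.random.default_rng(cfg.seed)
    rel_names = [f"R{t}" for t in range(cfg.n_rel_types)]
    ids = [f"C{i:04d}" for i in range(cfg.n_concepts)]
    rel_sets: list[set[str]] = [set()]
    child_count = np.zeros(cfg.n_concepts)
    edges: list[IsAEdge] = []
    for i in range(1, cfg.n_concepts):
        weights = child_count[:i] + 1.0
        p1 = int(rng.choice(i, p=weights / weights.sum()))
        parents = {p1}
        if i >= 2 and rng.random() < cfg.multi_parent_prob:
            p2 = int(rng.integers(i))
            if p2 != p1:
                parents.add(p2)
        s: set[str] = set()
        for p in parents:
            child_count[p] += 1
            edges.append(IsAEdge(ids[i], ids[p]))
            s |= rel_sets[p]
        if cfg.n_rel_types and rng.random() < cfg.mutation_prob:
            missing = [t for t in rel_names if t not in s]
            if missing:
                s.add(missing[int(rng.integers(len(missing)))])
        rel_sets.append(s)
    assertions = [
        LateralAssertion(ids[i], t, f"X{i:04d}.{t}")
        for i in range(cfg.n_concepts)
        for t in sorted(rel_sets[i])
    ]
    concepts = [Concept(ids[i], f"Synthetic concept {i}") for i in range(cfg.n_concepts)]
    return OntologyGraph(concepts, edges, assertions)


def build_gene_excerpt() -> OntologyGraph:
    """A 12-concept gene-hierarchy excerpt used as a worked example.

    The hierarchy is rooted at *Gene* and yields four areas: Ø (2
    concepts), *Gene Found In Organism* (2, rooted at *MicroRNA Gene*),
    *Gene Plays Role In Process* (4, single partial-area *Antigen Gene
    (4)*), and the two-type area {*Gene Found In Organism*, *Gene Plays
    Role In Process*} with two roots, giving partial-areas *GAGE6 wt
    Allele (1)* — child-of *Antigen Gene (4)* — and *CAGE1 wt Allele (3)*.
    Memberships beyond the named concepts are fixed by construction.
    """
    GFIO = "Gene Found In Organism"
    GPRIP = "Gene Plays Role In Process"
    concepts = [
        ("Gene", []),
        ("Regulatory Gene", []),
        ("MicroRNA Gene", [GFIO]),
        ("MIR1243 Gene", [GFIO]),
        ("Antigen Gene", [GPRIP]),
        ("GAGE6 Gene", [GPRIP]),
        ("CAGE1 Gene", [GPRIP]),
        ("XAGE1 Gene", [GPRIP]),
        ("GAGE6 wt Allele", [GFIO, GPRIP]),
        ("CAGE1 wt Allele", [GFIO, GPRIP]),
        ("CAGE1 wt Allele Variant 1", [GFIO, GPRIP]),
        ("CAGE1 wt Allele Variant 2", [GFIO, GPRIP]),
    ]
    edges = [
        ("Regulatory Gene", "Gene"),
        ("MicroRNA Gene", "Gene"),
        ("MIR1243 Gene", "MicroRNA Gene"),
        ("Antigen Gene", "Gene"),
        ("GAGE6 Gene", "Antigen Gene"),
        ("CAGE1 Gene", "Antigen Gene"),
        ("XAGE1 Gene", "Antigen Gene"),
        ("GAGE6 wt Allele", "GAGE6 Gene"),
        ("CAGE1 wt Allele", "CAGE1 Gene"),
        ("CAGE1 wt Allele Variant 1", "CAGE1 wt Allele"),
        ("CAGE1 wt Allele Variant 2", "CAGE1 wt Allele"),
    ]
    targets = {GFIO: "Organism", GPRIP: "Immune Response Process"}
    return OntologyGraph(
        [Concept(name, name) for name, _ in concepts],
        [IsAEdge(c, p) for c, p in edges],
        [
            LateralAssertion(name, t, targets[t])
            for name, types in concepts
            for t in types
        ],
    )


def plant_errors(
    g: OntologyGraph, pat: PartialAreaTaxonomy, model: PlantedErrorModel
) -> dict[str, bool]:
    """Plant independent per-concept ground-truth error flags.

    Each concept is flagged with the small-stratum rate if its
    partial-area size is at most ``model.bound``, else the large-stratum
    rate.
    """
    rng = np.random.default_rng(model.seed)
    sizes = pat.sizes_by_concept()
    flags: dict[str, bool] = {}
    for cid in g.concept_ids:
        rate = model.small_rate if sizes[cid] <= model.bound else model.large_rate
        flags[cid] = bool(rng.random() < rate)
    return flags


def simulate_audit(
    sample, truth: dict, auditor: AuditorModel = AuditorModel()
) -> list[AuditRecord]:
    """Produce audit records for a sample given ground truth and a reviewer model."""
    rng = np.random.default_rng(auditor.seed)
    records = []
    for cid in sample:
        t = truth[cid]
        flagged = rng.random() < (auditor.sensitivity if t else auditor.false_positive_rate)
        issue = "planted modelling error" if (flagged and t) else (
            "spurious finding" if flagged else ""
        )
        records.append(AuditRecord(cid, bool(flagged), issue))
    return records


def power_experiment(
    cfg: GeneratorConfig,
    model: PlantedErrorModel,
    n_small: int = 50,
    n_large: int = 50,
    reps: int = 500,
    seed: int = 0,
    auditor: AuditorModel = AuditorModel(),
    alpha: float = 0.05,
) -> float:
    """Monte-Carlo rejection rate of the end-to-end study design.

    One ontology is generated from ``cfg`` and its frame fixed; each
    replicate replants errors, redraws a proportional stratified sample
    of ``n_small`` + ``n_large`` concepts, simulates the audit, and tests
    the small-vs-large contingency at the planted bound with the
    two-tailed Fisher exact test.  Returns the fraction of replicates
    with p < ``alpha`` — the power under unequal planted rates, the
    type-I error rate under equal ones.
    """
    g = generate_ontology(cfg)
    pat = derive_partial_area_taxonomy(g)
    frame = build_frame(pat, exclude_overlapping=True, initial_bound=model.bound)
    allocation = allocate_proportional(frame, n_small, n_large)
    rng = np.random.default_rng(seed)
    rejections = 0
    for _ in range(reps):
        sub = int(rng.integers(2**31 - 1))
        truth = plant_errors(
            g, pat, PlantedErrorModel(model.small_rate, model.large_rate, model.bound, sub)
        )
        sample = draw_sample(frame, allocation, seed=sub + 1)
        records = simulate_audit(
            sample, truth,
            AuditorModel(auditor.sensitivity, auditor.false_positive_rate, sub + 2),
        )
        table = size_error_table(records, frame)
        ct = contingency_at_threshold(table, model.bound)
        if fisher_exact_two_tailed(ct) < alpha:
            rejections += 1
    return rejections / reps
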