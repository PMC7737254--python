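"""Blinded stratified audit sampling and error-rate statistics.

The QA study design: derive the partial-area taxonomy, exclude overlapping
concepts (known to be error-prone, which would bias the comparison), draw
a blinded stratified random sample of concepts from small and large
partial-areas, have a reviewer flag modelling errors without knowledge of
the hypothesis or strata, then tabulate errors by partial-area size, pick
the small/large threshold maximising statistical significance, and test
the 2×2 erroneous × small/large contingency with Fisher's exact test
(two-tailed, point-probability convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ontology import OntologyGraph
from .taxonomy import (
    PartialAreaTaxonomy,
    derive_partial_area_taxonomy,
    find_overlapping_concepts,
)

__all__ = [
    "SamplingFrame",
    "SampleAllocation",
    "AuditRecord",
    "SizeErrorTable",
    "ContingencyTable2x2",
    "ThresholdScanResult",
    "StudyConfig",
    "StudyReport",
    "build_frame",
    "allocate_proportional",
    "allocate_fixed_per_size",
    "draw_sample",
    "audit_worksheet",
    "read_audit_results",
    "size_error_table",
    "contingency_at_threshold",
    "fisher_exact_two_tailed",
    "select_threshold",
    "qa_study_report",
]

LARGE = "large"  # stratum key for concepts in partial-areas above the bound


@dataclass
class SamplingFrame:
    """Eligible concepts annotated with partial-area size and stratum.

    ``strata`` maps each eligible concept id to its partial-area size
    (small side) or to :data:`LARGE`; ``sizes`` maps every eligible
    concept to its numeric partial-area size; ``excluded`` lists the
    overlapping concepts dropped from the frame.
    """

    strata: dict
    sizes: dict
    bound: int
    excluded: frozenset = frozenset()

    def __len__(self) -> int:
        return len(self.strata)

    def population(self, stratum) -> list[str]:
        return sorted(c for c, s in self.strata.items() if s == stratum)

    @property
    def small_sizes(self) -> list[int]:
        return sorted({s for s in self.strata.values() if s != LARGE})


@dataclass
class SampleAllocation:
    """Per-size quotas for the small strata plus a quota for the large one."""

    per_size: dict  # size -> count
    n_large: int

    @property
    def total(self) -> int:
        return sum(self.per_size.values()) + self.n_large


@dataclass(frozen=True)
class AuditRecord:
    """One reviewer verdict on one sampled concept."""

    concept_id: str
    has_error: bool
    issue: str = ""
    suggested_correction: str = ""


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Erroneous / error-free counts for small vs large partial-areas.

    ``a`` small erroneous, ``b`` small error-free, ``c`` large erroneous,
    ``d`` large error-free.
    """

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self):
        for v in (self.a, self.b, self.c, self.d):
            if v < 0 or int(v) != v:
                raise ValueError("contingency cells must be nonnegative integers")

    @property
    def total(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def small_error_rate(self) -> float:
        return self.a / (self.a + self.b) if self.a + self.b else float("nan")

    @property
    def large_error_rate(self) -> float:
        return self.c / (self.c + self.d) if self.c + self.d else float("nan")


class SizeErrorTable:
    """Sampled and erroneous concept counts by partial-area size.

    Rows are keyed by integer size plus an optional aggregate ``>B``
    bucket holding everything above ``bound``.
    """

    def __init__(self, counts: Mapping, bound: int | None = None):
        self.bound = bound
        self.counts: dict = {}
        for key, (sampled, erroneous) in counts.items():
            if erroneous > sampled:
                raise ValueError(f"row {key!r}: erroneous {erroneous} > sampled {sampled}")
            self.counts[key] = (int(sampled), int(erroneous))

    @classmethod
    def from_counts(cls, counts: Mapping, bound: int | None = None) -> "SizeErrorTable":
        """Build from {size: (sampled, erroneous)}; key 'gt' (or '>B') is
        the aggregate bucket above ``bound``."""
        norm = {}
        for k, v in counts.items():
            if isinstance(k, str) and (k == "gt" or k.startswith(">")):
                norm["gt"] = v
            else:
                norm[int(k)] = v
        return cls(norm, bound)

    @property
    def n_sampled(self) -> int:
        return sum(s for s, _ in self.counts.values())

    @property
    def n_erroneous(self) -> int:
        return sum(e for _, e in self.counts.values())

    def sizes(self) -> list[int]:
        return sorted(k for k in self.counts if isinstance(k, int))

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for k in self.sizes():
            s, e = self.counts[k]
            rows.append((str(k), s, e, 100.0 * e / s if s else 0.0))
        if "gt" in self.counts:
            s, e = self.counts["gt"]
            label = f">{self.bound}" if self.bound is not None else ">max"
            rows.append((label, s, e, 100.0 * e / s if s else 0.0))
        rows.append(
            ("Total", self.n_sampled, self.n_erroneous,
             100.0 * self.n_erroneous / self.n_sampled if self.n_sampled else 0.0)
        )
        return pd.DataFrame(
            rows, columns=["size", "n_sampled", "n_erroneous", "error_pct"]
        )


@dataclass
class ThresholdScanResult:
    """Fisher p at each candidate bound, with the selected bound ``b_star``."""

    scan: pd.DataFrame  # columns: b, a, b_, c, d, p_value, small_rate, large_rate
    b_star: int

    @property
    def p_star(self) -> float:
        row = self.scan[self.scan["b"] == self.b_star].iloc[0]
        return float(row["p_value"])


# ---------------------------------------------------------------------------
# frame construction and sampling


def build_frame(
    pat: PartialAreaTaxonomy,
    exclude_overlapping: bool = True,
    initial_bound: int = 10,
) -> SamplingFrame:
    """Build the sampling frame of eligible concepts.

    Overlapping concepts (members of two or more partial-areas) are
    excluded by default.  Each eligible concept is annotated with its
    partial-area size and a stratum: the size itself if at most
    ``initial_bound``, else the single large stratum.  If exclusion is
    off, a concept with several containing partial-areas is assigned the
    smallest of their sizes.
    """
    if initial_bound < 1:
        raise ValueError("initial_bound must be >= 1")
    overlapping = find_overlapping_concepts(pat).overlapping if exclude_overlapping else set()
    sizes = pat.sizes_by_concept()
    strata: dict[str, object] = {}
    kept_sizes: dict[str, int] = {}
    for cid, size in sizes.items():
        if cid in overlapping:
            continue
        kept_sizes[cid] = size
        strata[cid] = size if size <= initial_bound else LARGE
    return SamplingFrame(strata, kept_sizes, initial_bound, frozenset(overlapping))


def allocate_proportional(
    frame: SamplingFrame, n_small: int, n_large: int
) -> SampleAllocation:
    """Split the small quota over sizes proportionally to population.

    Uses largest-remainder (Hamilton) rounding so the quotas sum exactly
    to ``n_small``; each quota differs from the exact proportional share
    by less than one.
    """
    pops = {s: len(frame.population(s)) for s in frame.small_sizes}
    total_small = sum(pops.values())
    if n_small > total_small:
        raise ValueError(
            f"small quota {n_small} exceeds small population {total_small}"
        )
    n_large_pop = len(frame.population(LARGE))
    if n_large > n_large_pop:
        raise ValueError(f"large quota {n_large} exceeds large population {n_large_pop}")
    exact = {s: n_small * p / total_small for s, p in pops.items() if p}
    quotas = {s: int(np.floor(v)) for s, v in exact.items()}
    # cap at population, then distribute the remainder by largest fraction
    for s in quotas:
        quotas[s] = min(quotas[s], pops[s])
    short = n_small - sum(quotas.values())
    order = sorted(exact, key=lambda s: (-(exact[s] - np.floor(exact[s])), s))
    while short > 0:
        progressed = False
        for s in order:
            if short == 0:
                break
            if quotas[s] < pops[s]:
                quotas[s] += 1
                short -= 1
                progressed = True
        if not progressed:  # pragma: no cover - guarded by population check
            raise ValueError("cannot satisfy small quota")
    return SampleAllocation({s: q for s, q in quotas.items() if q}, n_large)


def allocate_fixed_per_size(
    frame: SamplingFrame, quota_map: Mapping, n_large: int = 0
) -> SampleAllocation:
    """Fixed per-size quotas (e.g. 10 for size 1, 5 for sizes 2–10).

    A stratum smaller than its quota contributes all its members, with a
    warning; sizes absent from the frame are dropped silently — this is
    how a design like {1: 10, 2..10: 5 each} lands on a 50-concept small
    sample when one size has no partial-areas.
    """
    quotas = {}
    for size, q in quota_map.items():
        size = int(size)
        pop = len(frame.population(size))
        if pop == 0:
            continue
        if q > pop:
            warnings.warn(
                f"size-{size} stratum has only {pop} eligible concepts; "
                f"taking all (quota was {q})",
                stacklevel=2,
            )
            q = pop
        if q:
            quotas[size] = int(q)
    return SampleAllocation(quotas, int(n_large))


def draw_sample(
    frame: SamplingFrame, allocation: SampleAllocation, seed: int
) -> list[str]:
    """Draw the blinded sample: an ordered list of concept ids only.

    Uniform without-replacement draw within each stratum, then all strata
    shuffled together so the output reveals nothing about stratum or
    partial-area size.  Deterministic for a given seed.
    """
    rng = np.random.default_rng(seed)
    picked: list[str] = []
    strata = [(s, q) for s, q in sorted(allocation.per_size.items())]
    strata.append((LARGE, allocation.n_large))
    for stratum, quota in strata:
        pop = frame.population(stratum)
        if quota > len(pop):
            raise ValueError(
                f"quota {quota} exceeds population {len(pop)} in stratum {stratum!r}"
            )
        if quota:
            picked.extend(rng.choice(pop, size=quota, replace=False))
    return [str(c) for c in rng.permutation(picked)]


def audit_worksheet(sample: Sequence[str], g: OntologyGraph) -> pd.DataFrame:
    """Blinded worksheet for the reviewer: order, concept id, label only."""
    return pd.DataFrame(
        [(i + 1, cid, g.label(cid)) for i, cid in enumerate(sample)],
        columns=["order", "concept_id", "label"],
    )


def read_audit_results(source) -> list[AuditRecord]:
    """Read audit_results.tsv: concept_id, has_error (0/1), issue,
    suggested_correction (last two optional)."""
    df = pd.read_csv(source, sep="\t", dtype=str, keep_default_na=False)
    records = []
    for r in df.itertuples(index=False):
        records.append(
            AuditRecord(
                r.concept_id,
                str(r.has_error).strip() in ("1", "true", "True"),
                getattr(r, "issue", ""),
                getattr(r, "suggested_correction", ""),
            )
        )
    return records


# ---------------------------------------------------------------------------
# statistics


def size_error_table(
    records: Iterable[AuditRecord], frame: SamplingFrame
) -> SizeErrorTable:
    """Tabulate sampled and erroneous concepts by partial-area size.

    Sizes above the frame's bound are pooled into the ``>B`` bucket.
    Every record must refer to a concept in the frame.
    """
    counts: dict = {}
    for rec in records:
        if rec.concept_id not in frame.sizes:
            raise KeyError(f"audit record for concept not in frame: {rec.concept_id!r}")
        size = frame.sizes[rec.concept_id]
        key = size if size <= frame.bound else "gt"
        s, e = counts.get(key, (0, 0))
        counts[key] = (s + 1, e + int(rec.has_error))
    return SizeErrorTable(counts, frame.bound)


def contingency_at_threshold(t: SizeErrorTable, b: int) -> ContingencyTable2x2:
    """Collapse the per-size table at bound ``b``: sizes ≤ b are small."""
    if t.bound is not None and b > t.bound:
        raise ValueError(f"bound {b} exceeds tabulated range (> {t.bound} is pooled)")
    a = bb = c = d = 0
    for key, (sampled, err) in t.counts.items():
        small = isinstance(key, int) and key <= b
        if small:
            a += err
            bb += sampled - err
        else:
            c += err
            d += sampled - err
    return ContingencyTable2x2(a, bb, c, d)


def fisher_exact_two_tailed(ct: ContingencyTable2x2) -> float:
    """Two-tailed Fisher exact p for a 2×2 table.

    Point-probability convention: the sum, over all tables with the
    observed margins, of hypergeometric point probabilities not exceeding
    that of the observed table (the convention of R's ``fisher.test``).
    """
    if ct.total == 0:
        raise ValueError("all-zero contingency table")
    return float(
        stats.fisher_exact([[ct.a, ct.b], [ct.c, ct.d]], alternative="two-sided")[1]
    )


def select_threshold(
    t: SizeErrorTable, candidates: Iterable[int] | None = None
) -> ThresholdScanResult:
    """Scan candidate bounds and select the one minimising the Fisher p.

    Default candidates are 1..10 (clipped to the tabulated range).  Ties
    are broken toward the smallest bound, preferring the stronger
    small-partial-area claim.
    """
    if candidates is None:
        hi = t.bound if t.bound is not None else max(t.sizes(), default=1)
        candidates = range(1, hi + 1)
    candidates = sorted(set(int(b) for b in candidates))
    if t.bound is not None:
        candidates = [b for b in candidates if b <= t.bound]
    if not candidates:
        raise ValueError("no candidate bounds")
    rows = []
    for b in candidates:
        ct = contingency_at_threshold(t, b)
        p = fisher_exact_two_tailed(ct) if ct.total else float("nan")
        rows.append(
            (b, ct.a, ct.b, ct.c, ct.d, p, ct.small_error_rate, ct.large_error_rate)
        )
    scan = pd.DataFrame(
        rows,
        columns=["b", "a", "b_", "c", "d", "p_value", "small_rate", "large_rate"],
    )
    b_star = int(scan.loc[scan["p_value"].idxmin(), "b"])  # idxmin: first minimum
    return ThresholdScanResult(scan, b_star)


# ---------------------------------------------------------------------------
# end-to-end study


@dataclass
class StudyConfig:
    """Parameters of a small partial-area QA study."""

    initial_bound: int = 10
    exclude_overlapping: bool = True
    candidates: tuple = tuple(range(1, 11))
    alpha: float = 0.05
    mode: str = "asserted"


@dataclass
class StudyReport:
    """Structured result of :func:`qa_study_report`."""

    frame: SamplingFrame
    table: SizeErrorTable
    scan: ThresholdScanResult
    contingency: ContingencyTable2x2
    p_value: float
    b_star: int
    supported: bool
    alpha: float

    def render(self) -> str:
        lines = [
            "Small partial-area QA study",
            "===========================",
            f"eligible concepts: {len(self.frame)} "
            f"(excluded overlapping: {len(self.frame.excluded)})",
            f"sampled: {self.table.n_sampled}, erroneous: {self.table.n_erroneous}",
            "",
            self.table.to_frame().to_string(index=False),
            "",
            "threshold scan:",
            self.scan.scan.to_string(index=False),
            "",
            f"selected bound b* = {self.b_star}",
            f"contingency (a,b,c,d) = ({self.contingency.a}, {self.contingency.b}, "
            f"{self.contingency.c}, {self.contingency.d})",
            f"small error rate = {100 * self.contingency.small_error_rate:.1f}%, "
            f"large error rate = {100 * self.contingency.large_error_rate:.1f}%",
            f"two-tailed Fisher exact p = {self.p_value:.4f}",
            (
                f"Hypothesis 1 supported at b*={self.b_star} (p < {self.alpha})"
                if self.supported
                else f"Hypothesis 1 NOT supported (p >= {self.alpha})"
            ),
        ]
        return "\n".join(lines)


def qa_study_report(
    g: OntologyGraph,
    records: Iterable[AuditRecord],
    config: StudyConfig = StudyConfig(),
    pat: PartialAreaTaxonomy | None = None,
) -> StudyReport:
    """Run the full analysis on already-audited records.

    Derives the taxonomy (unless one is supplied), builds the frame,
    tabulates errors by size, scans thresholds, and tests the selected
    contingency: the small-partial-area hypothesis is *supported at b**
    iff the two-tailed Fisher p at the selected bound is below alpha.
    """
    if pat is None:
        pat = derive_partial_area_taxonomy(g, config.mode)
    frame = build_frame(pat, config.exclude_overlapping, config.initial_bound)
    table = size_error_table(records, frame)
    scan = select_threshold(table, config.candidates)
    ct = contingency_at_threshold(table, scan.b_star)
    p = fisher_exact_two_tailed(ct)
    return StudyReport(
        frame, table, scan, ct, p, scan.b_star, bool(p < config.alpha), config.alpha
    )
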