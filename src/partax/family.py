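"""Family-level applicability statistics for QA techniques.

Whether a QA technique works on a given ontology is treated as an
independent Bernoulli trial with success probability ``p``; a series of
studies on ontologies from one structural family is then binomial.  The
technique is declared applicable to at least half of the family when the
exact (Clopper–Pearson) central 95% confidence interval on ``p`` lies
entirely above 0.5 — which first happens at six successes out of six
studies, eight of nine, ten of twelve, and so on.

Structural families are keyed on two features of an ontology hierarchy:
whether it has any lateral relationships (object properties) and whether
its is-a structure is a tree or a proper DAG (some concept with multiple
parents).
"""

from __future__ import annotations

from dataclasses import dataclass

from scipy import stats

from .ontology import OntologyGraph

__all__ = [
    "BinomialExperiment",
    "ExactCI",
    "StructuralFeatures",
    "binomial_pmf",
    "clopper_pearson_ci",
    "min_studies_required",
    "family_applicability",
    "ApplicabilityDecision",
    "classify_structural_family",
]


@dataclass(frozen=True)
class BinomialExperiment:
    """``n`` independent studies with ``i`` successes at probability ``p``."""

    n: int
    i: int
    p: float

    def __post_init__(self):
        if not (0 <= self.i <= self.n):
            raise ValueError(f"need 0 <= i <= n, got i={self.i}, n={self.n}")
        if not (0.0 <= self.p <= 1.0):
            raise ValueError(f"need 0 <= p <= 1, got {self.p}")


@dataclass(frozen=True)
class ExactCI:
    """Exact central binomial confidence interval on a probability."""

    lower: float
    upper: float
    confidence: float


@dataclass(frozen=True)
class StructuralFeatures:
    """Feature pair defining an ontology's structural family."""

    has_object_properties: bool
    hierarchy_is_dag_with_multiparents: bool

    @property
    def family_label(self) -> str:
        op = "OP" if self.has_object_properties else "noOP"
        shape = "DAG" if self.hierarchy_is_dag_with_multiparents else "tree"
        return f"{op}+{shape}"


@dataclass(frozen=True)
class ApplicabilityDecision:
    """Family-applicability verdict with its supporting interval."""

    successes: int
    n: int
    ci: ExactCI
    p0: float
    applicable: bool


def binomial_pmf(e: BinomialExperiment) -> float:
    """Probability of exactly ``i`` successes in ``n`` trials: C(n,i) p^i (1-p)^(n-i)."""
    return float(stats.binom.pmf(e.i, e.n, e.p))


def clopper_pearson_ci(i: int, n: int, confidence: float = 0.95) -> ExactCI:
    """Exact central (Clopper–Pearson) binomial confidence interval.

    Uses the beta-quantile characterisation: the lower endpoint is the
    alpha/2 quantile of Beta(i, n-i+1) (0 when i = 0) and the upper the
    1-alpha/2 quantile of Beta(i+1, n-i) (1 when i = n).  Chosen over
    normal approximations because family sizes are small, and over
    shorter asymmetric intervals to be conservative.
    """
    if n < 1 or not (0 <= i <= n):
        raise ValueError(f"need n >= 1 and 0 <= i <= n, got i={i}, n={n}")
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must be in (0, 1)")
    alpha = 1.0 - confidence
    lower = 0.0 if i == 0 else float(stats.beta.ppf(alpha / 2.0, i, n - i + 1))
    upper = 1.0 if i == n else float(stats.beta.ppf(1.0 - alpha / 2.0, i + 1, n - i))
    return ExactCI(lower, upper, confidence)


def min_studies_required(
    f: int, p0: float = 0.5, confidence: float = 0.95
) -> int:
    """Smallest number of studies establishing family applicability.

    Returns the minimal ``n`` such that with ``n - f`` successes out of
    ``n`` the Clopper–Pearson lower bound exceeds ``p0``: 6 studies when
    all succeed, 9 when one may fail, 12 when two may fail.
    """
    if f < 0:
        raise ValueError("allowed failures must be >= 0")
    n = max(f + 1, 1)
    while True:
        if clopper_pearson_ci(n - f, n, confidence).lower > p0:
            return n
        n += 1


def family_applicability(
    successes: int, n: int, p0: float = 0.5, confidence: float = 0.95
) -> ApplicabilityDecision:
    """Decide applicability to at least a fraction ``p0`` of the family.

    The criterion is strict exclusion of ``p0``: the exact lower
    confidence bound on the per-ontology success probability must exceed
    ``p0``.
    """
    ci = clopper_pearson_ci(successes, n, confidence)
    return ApplicabilityDecision(successes, n, ci, p0, bool(ci.lower > p0))


def classify_structural_family(g: OntologyGraph) -> StructuralFeatures:
    """Classify a hierarchy by the features governing QA applicability.

    ``has_object_properties`` is true iff any lateral assertion exists
    (required for partial-area taxonomies to be non-trivial);
    ``hierarchy_is_dag_with_multiparents`` is true iff some concept has
    two or more parents (required for overlapping concepts to exist).
    """
    has_op = bool(g.assertions)
    multi = any(len(g.parents(c)) >= 2 for c in g.concept_ids)
    return StructuralFeatures(has_op, multi)
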