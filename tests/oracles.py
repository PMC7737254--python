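"""Independent brute-force oracles used to check the implementation.

These deliberately take different computational routes from the package:
set unions over explicitly enumerated ancestors, bucketing plus pairwise
parent scans for areas, reachability on induced subgraphs for
partial-areas, and exact-fraction hypergeometric enumeration for the
two-tailed Fisher test.
"""

from __future__ import annotations

from fractions import Fraction
from math import comb

import networkx as nx


def ancestors_by_dfs(parents: dict[str, set[str]], cid: str) -> set[str]:
    """All strict ancestors of cid via explicit DFS over the parent map."""
    seen: set[str] = set()
    stack = list(parents.get(cid, ()))
    while stack:
        p = stack.pop()
        if p not in seen:
            seen.add(p)
            stack.extend(parents.get(p, ()))
    return seen


def inherited_sets_bruteforce(g) -> dict[str, frozenset]:
    """Union of asserted sets over self and all ancestors, per concept."""
    parents = {c: g.parents(c) for c in g.concept_ids}
    out = {}
    for c in g.concept_ids:
        s = set(g.asserted_rel_types(c))
        for a in ancestors_by_dfs(parents, c):
            s |= g.asserted_rel_types(a)
        out[c] = frozenset(s)
    return out


def descendants_bruteforce(g, cid: str) -> set[str]:
    """Transitive closure below cid via DFS over the child map."""
    children = {c: g.children(c) for c in g.concept_ids}
    seen: set[str] = set()
    stack = list(children[cid])
    while stack:
        c = stack.pop()
        if c not in seen:
            seen.add(c)
            stack.extend(children[c])
    return seen


def areas_bruteforce(g, mode: str = "asserted"):
    """Bucket concepts by frozen rel-type set; scan all parent pairs for links.

    Returns (buckets: key -> member set, roots: key -> root set,
    links: {(child key, parent key)}).
    """
    eff = g.effective_rel_types(mode)
    buckets: dict[frozenset, set[str]] = {}
    for c in g.concept_ids:
        buckets.setdefault(eff[c], set()).add(c)
    roots = {
        k: {c for c in mem if all(eff[p] != k for p in g.parents(c))}
        for k, mem in buckets.items()
    }
    links = {
        (k, eff[p])
        for k, rs in roots.items()
        for r in rs
        for p in g.parents(r)
    }
    return buckets, roots, links


def partial_area_members_bruteforce(g, mode: str = "asserted"):
    """root id -> member set, via reachability on the induced in-area subgraph."""
    buckets, roots, _ = areas_bruteforce(g, mode)
    out: dict[str, set[str]] = {}
    for k, mem in buckets.items():
        sub = nx.DiGraph()
        sub.add_nodes_from(mem)
        for c in mem:
            for ch in g.children(c):
                if ch in mem:
                    sub.add_edge(c, ch)  # parent -> child
        for r in roots[k]:
            out[r] = {m for m in mem if nx.has_path(sub, r, m)}
    return out


def fisher_two_tailed_enumeration(a: int, b: int, c: int, d: int) -> float:
    """Exact two-tailed Fisher p by enumerating the hypergeometric support.

    Point-probability convention with exact rational arithmetic: sum the
    probabilities of all tables (with the observed margins) whose point
    probability does not exceed the observed one.
    """
    n = a + b + c + d
    r1 = a + b
    c1 = a + c
    denom = comb(n, c1)

    def point(k: int) -> Fraction:
        return Fraction(comb(r1, k) * comb(n - r1, c1 - k), denom)

    lo = max(0, c1 - (n - r1))
    hi = min(r1, c1)
    p_obs = point(a)
    cutoff = p_obs + p_obs * Fraction(1, 10**7)
    return float(sum(point(k) for k in range(lo, hi + 1) if point(k) <= cutoff))


def binom_tail_ge(n: int, k: int, p: float) -> float:
    """P(X >= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


def binom_tail_le(n: int, k: int, p: float) -> float:
    """P(X <= k) for X ~ Binomial(n, p), by direct summation."""
    return sum(comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(0, k + 1))
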