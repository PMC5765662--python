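"""Brute-force reference implementations used only as test oracles.

Deliberately naive and independent of the library's graph machinery
(no networkx): ancestry by fixed-point closure over the raw edge set,
minimal common ancestors by pairwise enumeration, reachability by
depth-first search over explicit edge lists.
"""

from itertools import combinations


def closure_ancestors(edges, term):
    """Proper ancestors of ``term`` by fixed-point iteration over (child, parent)."""
    out = set()
    frontier = {p for c, p in edges if c == term}
    while frontier:
        out |= frontier
        frontier = {p for c, p in edges if c in frontier} - out
    return out


def closure_descendants(edges, term):
    return closure_ancestors([(p, c) for c, p in edges], term)


def brute_minimal_common_ancestors(edges, low_terms, top_term):
    """Union over pairs of low terms of their minimal common proper ancestors,
    restricted to proper descendants of ``top_term`` and excluding the low
    terms themselves."""
    low = sorted(set(low_terms))
    anc = {t: closure_ancestors(edges, t) for t in low}
    result = set()
    for a, b in combinations(low, 2):
        common = anc[a] & anc[b]
        minimal = {
            x
            for x in common
            if not any(y != x and x in closure_ancestors(edges, y) for y in common)
        }
        result |= minimal
    below_top = {
        x for x in result if x != top_term and top_term in closure_ancestors(edges, x)
    }
    return below_top - set(low)


def reachable(edges, start, goal):
    """Is ``goal`` reachable from ``start`` along (child, parent) edges?"""
    seen = set()
    stack = [start]
    while stack:
        node = stack.pop()
        if node == goal:
            return True
        if node in seen:
            continue
        seen.add(node)
        stack.extend(p for c, p in edges if c == node)
    return False
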