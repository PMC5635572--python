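"""Independent brute-force oracles used by the unit and acceptance tests.

These deliberately avoid the package's own graph/overlap code paths:
reachability is computed by repeated edge relaxation, containment by an
all-window token scan, so agreement with the optimized implementations is
a genuine dual-route check.
"""

from __future__ import annotations

from obosyn.obo_io import OntologyModel


def brute_reachability(edges: set[tuple[str, str]]) -> set[tuple[str, str]]:
    """Transitive closure of (parent, child) edges by repeated relaxation."""
    closure = set(edges)
    changed = True
    while changed:
        changed = False
        for a, b in list(closure):
            for c, d in list(closure):
                if b == c and (a, d) not in closure:
                    closure.add((a, d))
                    changed = True
    return closure


def brute_min_depth(
    edges: set[tuple[str, str]], ancestor: str, descendant: str
) -> int:
    """Shortest chain length from ancestor to descendant by breadth-first
    expansion over raw edge tuples."""
    frontier = {ancestor}
    depth = 0
    seen = {ancestor}
    while frontier:
        depth += 1
        nxt = {d for (p, d) in edges if p in frontier} - seen
        if descendant in nxt:
            return depth
        seen |= nxt
        frontier = nxt
    raise AssertionError(f"{descendant} not reachable from {ancestor}")


def brute_window_contains(
    big: tuple[str, ...], small: tuple[str, ...], proper: bool
) -> bool:
    """All-window scan for contiguous token-subsequence containment."""
    if proper and len(big) <= len(small):
        return False
    if len(small) == 0 or len(small) > len(big):
        return False
    for i in range(len(big) - len(small) + 1):
        if all(big[i + j] == small[j] for j in range(len(small))):
            return True
    return False


def alive_edges(model: OntologyModel) -> set[tuple[str, str]]:
    alive = {t.id for t in model.non_obsolete()}
    return {
        (p, t.id)
        for t in model.non_obsolete()
        for p in t.parents
        if p in alive
    }


def brute_overlap_identities(
    model: OntologyModel, excluded_ancestors: set[str] | None = None
) -> set[tuple[str, str, str, str]]:
    """Quadratic all-pairs scan: closure pairs x synonym pairs, token-window
    containment; identities as (anc_id, desc_id, anc_norm, desc_norm)."""
    from obosyn.textnorm import normalize_phrase

    excluded = excluded_ancestors or set()
    closure = brute_reachability(alive_edges(model))
    out: set[tuple[str, str, str, str]] = set()
    for a, d in closure:
        if a in excluded:
            continue
        for ea in model.terms[a].synonym_entries():
            for ed in model.terms[d].synonym_entries():
                pa = normalize_phrase(ea.text)
                pd = normalize_phrase(ed.text)
                if brute_window_contains(pd.tokens, pa.tokens, proper=True):
                    out.add((a, d, pa.normalized, pd.normalized))
    return out


def shortest_first_split(texts: list[str], k: int) -> tuple[list[str], list[str]]:
    """Split candidate strings into (planted, absent) with the k shortest
    (by token count) planted.  Containment among generated strings always
    has the container strictly longer, so no absent phrase can occur
    inside a planted one — planting is then free of accidental hits."""
    ordered = sorted(texts, key=lambda t: (len(t.split()), t))
    return ordered[:k], ordered[k:]


def category_excluded_ancestors(model: OntologyModel) -> set[str]:
    """With a unique root the categories are its children; overlaps
    anchored at the root itself are out of scope."""
    roots = model.roots
    return set(roots) if len(roots) == 1 else set()
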