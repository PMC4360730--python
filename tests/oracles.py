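"""Independent brute-force oracles.

These work directly on raw (terms, relationships) lists — never through
OntologyGraph / networkx — so they stay independent of the code paths they
check. All are deliberately naive: plain breadth-first reachability, DFS
coloring, linear scans.
"""

from __future__ import annotations

import re
from collections import deque

from ontoslim.model import OntologyTerm, Relationship


def adjacency(rels: list[Relationship], relations: set[str],
              known: set[str]) -> dict[str, set[str]]:
    adj: dict[str, set[str]] = {}
    for r in rels:
        if r.predicate in relations and r.subject in known and r.object in known:
            adj.setdefault(r.subject, set()).add(r.object)
    return adj


def oracle_ancestors(terms: list[OntologyTerm], rels: list[Relationship],
                     start: str, relations: set[str]) -> set[str]:
    """Breadth-first reachability over edges with allowed predicates."""
    known = {t.id for t in terms}
    adj = adjacency(rels, relations, known)
    seen: set[str] = set()
    queue = deque(adj.get(start, ()))
    while queue:
        node = queue.popleft()
        if node in seen:
            continue
        seen.add(node)
        queue.extend(adj.get(node, ()))
    seen.discard(start)
    return seen


def oracle_has_cycle(terms: list[OntologyTerm], rels: list[Relationship],
                     relations: set[str]) -> bool:
    """Standard DFS white/grey/black coloring."""
    known = {t.id for t in terms}
    adj = adjacency(rels, relations, known)
    WHITE, GREY, BLACK = 0, 1, 2
    color = {t: WHITE for t in known}

    def visit(node: str) -> bool:
        color[node] = GREY
        for nxt in adj.get(node, ()):
            if color[nxt] == GREY:
                return True
            if color[nxt] == WHITE and visit(nxt):
                return True
        color[node] = BLACK
        return False

    return any(color[t] == WHITE and visit(t) for t in known)


def oracle_slims(terms: list[OntologyTerm], rels: list[Relationship],
                 start: str, members: set[str], relations: set[str]) -> set[str]:
    """Slim members among the reachable set plus the term itself."""
    reach = oracle_ancestors(terms, rels, start, relations) | {start}
    return reach & members


def _norm(text: str) -> str:
    return " ".join(re.sub(r"[^\w\s]", " ", text.lower()).split())


def oracle_search(terms: list[OntologyTerm], query: str) -> set[str]:
    """Linear scan: term ids whose name or any synonym contains the
    normalized query as a substring (non-obsolete terms only)."""
    q = _norm(query)
    if not q:
        return set()
    out = set()
    for term in terms:
        if term.obsolete:
            continue
        for text in [term.name, *term.synonym_texts()]:
            if q in _norm(text):
                out.add(term.id)
                break
    return out


def oracle_record_search(records, terms, rels, query: str) -> set[str]:
    """Hits plus records whose annotated-term ancestor set intersects the
    hit set."""
    hits = oracle_search(terms, query)
    relations = {"is_a", "part_of", "derives_from"}
    known = {t.id for t in terms}
    matched = set()
    for record in records:
        for tid in [record.biosample_term, record.assay_term, *record.treatment_terms]:
            if tid is None or tid not in known:
                continue
            if tid in hits or oracle_ancestors(terms, rels, tid, relations) & hits:
                matched.add(record.record_id)
                break
    return matched
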