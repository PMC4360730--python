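"""Name- and synonym-expanded term search.

Free-text search over a merged ontology graph: every non-obsolete term is
findable by its official name *and* by any of its synonyms, so a query for
"breast" finds both the term named "breast" and the term "mammary tissue"
whose synonym is "lobe of breast". Record search additionally follows
inferred relationships: an experiment annotated to a child term is returned
for a query matching any of the child's ancestors.

Matching is deterministic token matching (no fuzziness): text is
case-folded, punctuation-stripped and whitespace-collapsed, then a query
scores 1.0 on an exact full-string match, 0.8 when it appears as a whole
token (or contiguous token run), and 0.5 when it is a substring. The
numeric levels are an artifact convention; only their monotone order
matters.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

from .graph import OntologyGraph
from .model import CORE_RELATIONS

_PUNCT_RE = re.compile(r"[^\w\s]", re.UNICODE)

SCORE_EXACT = 1.0
SCORE_TOKEN = 0.8
SCORE_SUBSTRING = 0.5


def normalize(text: str) -> str:
    """Case-fold, strip punctuation, collapse whitespace."""
    return " ".join(_PUNCT_RE.sub(" ", text.casefold()).split())


@dataclass(frozen=True)
class SearchHit:
    """One matching term: which text matched and how specifically."""

    term: str
    matched_text: str
    match_kind: str  # "name" | "synonym"
    score: float


@dataclass(frozen=True)
class _IndexedText:
    term: str
    text: str
    kind: str
    norm: str


class SearchIndex:
    """Searchable view over a graph's non-obsolete names and synonyms."""

    def __init__(self, graph: OntologyGraph):
        self.graph = graph
        self._texts: list[_IndexedText] = []
        for tid in sorted(graph.terms):
            term = graph.terms[tid]
            if term.obsolete:
                continue
            self._texts.append(_IndexedText(tid, term.name, "name", normalize(term.name)))
            for syn in term.synonyms:
                self._texts.append(
                    _IndexedText(tid, syn.text, "synonym", normalize(syn.text))
                )

    def __len__(self) -> int:
        return len(self._texts)

    def texts(self) -> list[_IndexedText]:
        return list(self._texts)


def build_search_index(graph: OntologyGraph) -> SearchIndex:
    """Index every non-obsolete term's name and synonyms for search."""
    return SearchIndex(graph)


def score_match(query_norm: str, text_norm: str) -> float | None:
    """Score of a normalized query against one normalized text, or None."""
    if not query_norm:
        return None
    if query_norm == text_norm:
        return SCORE_EXACT
    if f" {query_norm} " in f" {text_norm} ":
        return SCORE_TOKEN
    if query_norm in text_norm:
        return SCORE_SUBSTRING
    return None


def search(index: SearchIndex, query: str) -> list[SearchHit]:
    """All terms whose name or any synonym matches *query*.

    One hit per term, carrying its best-scoring matched text (names beat
    synonyms on ties); hits sorted by score descending, then term id. An
    empty query returns no hits.
    """
    qn = normalize(query)
    if not qn:
        return []
    best: dict[str, SearchHit] = {}
    for item in index.texts():
        score = score_match(qn, item.norm)
        if score is None:
            continue
        cur = best.get(item.term)
        # prefer higher score; on equal score prefer a name over a synonym
        if cur is None or score > cur.score or (
            score == cur.score and cur.match_kind == "synonym" and item.kind == "name"
        ):
            best[item.term] = SearchHit(item.term, item.text, item.kind, score)
    return sorted(best.values(), key=lambda h: (-h.score, h.term))


def search_records(
    records: Sequence,
    index: SearchIndex,
    query: str,
    relations: Iterable[str] = CORE_RELATIONS,
) -> list[str]:
    """Ids of records whose any annotated term matches *query*, directly or
    through an inferred relationship (an ancestor of the annotated term is a
    hit).

    Records referencing ids absent from the graph are kept in play for their
    other annotations; the unknown ids simply cannot match.
    """
    hit_ids = {h.term for h in search(index, query)}
    if not hit_ids:
        return []
    graph = index.graph
    rels = set(relations)
    out = []
    for record in records:
        terms = [record.biosample_term, record.assay_term, *record.treatment_terms]
        matched = False
        for tid in terms:
            if tid is None:
                continue
            resolved, _ = graph.resolve(tid)
            if resolved is None:
                continue
            if resolved in hit_ids or graph.ancestors(resolved, rels) & hit_ids:
                matched = True
                break
        if matched:
            out.append(record.record_id)
    return out
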