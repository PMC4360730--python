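"""Typed-relation DAG services: closure, inference, cycle and root detection.

An :class:`OntologyGraph` is a merged multi-ontology graph whose edges carry
relationship predicates. Traversal always runs child -> parent (an edge
``liver is_a organ`` points from the specific term to the more general one),
so "ancestors" are the terms reachable along outgoing edges.

The scientifically interesting part is *inferred relationships*: a path of
explicit typed edges composes into a single predicate. E.g. a cell line that
``is_a`` hepatoma cell line which ``derives_from`` hepatocytes is itself
derived from hepatocytes. The composition table lives in
:func:`compose_predicates`.
"""

from __future__ import annotations

from collections import deque
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import networkx as nx

from .errors import CycleError, UnknownTermError
from .model import CORE_RELATIONS, OntologyTerm, Relationship

#: Deterministic preference order when parallel edges of different predicates
#: link the same pair of terms along an inference path.
_PREDICATE_ORDER = {"is_a": 0, "part_of": 1, "derives_from": 2}


def compose_predicates(first: str, then: str) -> str | None:
    """Compose two core predicates along a path (``first`` edge, ``then`` edge).

    Rules: ``is_a`` is the identity on either side; ``derives_from`` anywhere
    in the chain dominates (derivation inherits a significant biological
    portion, so any further generalisation or containment preserves it);
    ``part_of`` composed with ``part_of`` stays ``part_of``. Any non-core
    label breaks the chain (returns None).
    """
    if first not in CORE_RELATIONS or then not in CORE_RELATIONS:
        return None
    if first == "is_a":
        return then
    if then == "is_a":
        return first
    if "derives_from" in (first, then):
        return "derives_from"
    return "part_of"  # part_of . part_of


@dataclass
class OntologyGraph:
    """Merged typed-edge DAG with closure services.

    Attributes
    ----------
    terms:
        CURIE -> :class:`OntologyTerm` for every defined node.
    dangling:
        Edges whose object id is defined in no merged part; kept for
        reporting but never traversed.
    aliases:
        obsolete CURIE -> replacement CURIE (from ``replaced_by``).
    warnings:
        Human-readable merge diagnostics (name conflicts, cycles under the
        ``warn`` policy, ...).
    excluded:
        Terms on a core-relation cycle when the cycle policy is ``warn``;
        they are removed from all closure computations.
    """

    terms: dict[str, OntologyTerm] = field(default_factory=dict)
    dangling: list[Relationship] = field(default_factory=list)
    aliases: dict[str, str] = field(default_factory=dict)
    warnings: list[str] = field(default_factory=list)
    excluded: set[str] = field(default_factory=set)
    _g: nx.MultiDiGraph = field(default_factory=nx.MultiDiGraph, repr=False)

    # -- construction -----------------------------------------------------

    def add_term(self, term: OntologyTerm) -> None:
        self.terms[term.id] = term
        self._g.add_node(term.id)

    def add_edge(self, rel: Relationship) -> None:
        """Add one relationship edge; dangling objects are flagged, not added."""
        if rel.object not in self.terms:
            self.dangling.append(rel)
            return
        # MultiDiGraph keyed by predicate: parallel edges with distinct
        # predicates coexist; re-adding the same (s, o, predicate) is a no-op.
        self._g.add_edge(rel.subject, rel.object, key=rel.predicate)

    # -- basic queries -----------------------------------------------------

    def __contains__(self, term_id: str) -> bool:
        return term_id in self.terms

    def __len__(self) -> int:
        return len(self.terms)

    def _require(self, term_id: str) -> None:
        if term_id not in self.terms:
            raise UnknownTermError(term_id)

    def resolve(self, term_id: str) -> tuple[str | None, bool]:
        """Resolve an annotated id, following ``replaced_by`` once.

        Returns ``(resolved_id, remapped)``; ``(None, False)`` if the id is
        absent and has no usable replacement.
        """
        if term_id in self.terms and not self.terms[term_id].obsolete:
            return term_id, False
        target = self.aliases.get(term_id)
        if target is not None and target in self.terms:
            return target, True
        return None, False

    def out_edges(self, term_id: str) -> Iterator[Relationship]:
        """Resolvable outgoing edges of a term (dangling ones excluded)."""
        for _, obj, pred in self._g.out_edges(term_id, keys=True):
            yield Relationship(term_id, pred, obj)

    def edges(self) -> Iterator[Relationship]:
        for sub, obj, pred in self._g.edges(keys=True):
            yield Relationship(sub, pred, obj)

    def n_edges(self) -> int:
        return self._g.number_of_edges()

    # -- closure -----------------------------------------------------------

    def _view(self, relations: Iterable[str]) -> nx.MultiDiGraph:
        rels = set(relations)
        return nx.subgraph_view(
            self._g,
            filter_node=lambda n: n not in self.excluded,
            filter_edge=lambda u, v, k: k in rels,
        )

    def ancestors(self, term_id: str, relations: Iterable[str] = CORE_RELATIONS) -> set[str]:
        """All terms reachable from *term_id* along >= 1 edge whose predicate
        is in *relations*; the term itself is excluded."""
        self._require(term_id)
        if term_id in self.excluded:
            return set()
        return set(nx.descendants(self._view(relations), term_id))

    def infer_relationship(self, from_id: str, to_id: str) -> str | None:
        """Predicate of the inferred relationship ``from_id -> to_id``.

        Composes explicit core-relation predicates along a shortest directed
        path (ties broken by the lexicographically smallest node sequence;
        parallel predicates on one hop by ``is_a < part_of < derives_from``).
        Returns None when no core-relation path exists or the pair is equal.
        """
        self._require(from_id)
        self._require(to_id)
        if from_id == to_id:
            return None
        view = self._view(CORE_RELATIONS)
        if from_id in self.excluded or to_id in self.excluded:
            return None
        try:
            path = min(nx.all_shortest_paths(view, from_id, to_id))
        except (nx.NetworkXNoPath, nx.NodeNotFound):
            return None
        label: str | None = None
        for u, v in zip(path, path[1:]):
            pred = min(view[u][v], key=_PREDICATE_ORDER.__getitem__)
            label = pred if label is None else compose_predicates(label, pred)
            if label is None:  # pragma: no cover - view carries core keys only
                return None
        return label

    def detect_cycles(self) -> list[list[str]]:
        """Directed cycles over the core relations, each as its member ids in
        traversal order; empty list iff the core graph is acyclic."""
        rels = CORE_RELATIONS
        view = nx.subgraph_view(self._g, filter_edge=lambda u, v, k: k in rels)
        return [list(c) for c in nx.simple_cycles(view)]

    def roots(self, relations: Iterable[str] = CORE_RELATIONS) -> set[str]:
        """Non-obsolete terms with no resolvable outgoing edge in *relations*.

        Edges whose object is dangling do not disqualify a term from being a
        root: an unresolvable id contributes no knowledge, so a term whose
        only parents are dangling is still a top of the known hierarchy.
        """
        rels = set(relations)
        out: set[str] = set()
        for tid, term in self.terms.items():
            if term.obsolete:
                continue
            if not any(r.predicate in rels for r in self.out_edges(tid)):
                out.add(tid)
        return out

    # -- assembly checks ---------------------------------------------------

    def enforce_acyclic(self, policy: str = "error") -> None:
        """Check the DAG invariant.

        ``policy="error"``: raise :class:`CycleError` on any core cycle.
        ``policy="warn"``: record a warning and exclude cyclic terms from
        closure computations.
        """
        cycles = self.detect_cycles()
        if not cycles:
            return
        if policy == "error":
            raise CycleError(cycles)
        members = {t for c in cycles for t in c}
        self.excluded |= members
        self.warnings.append(
            f"{len(cycles)} cycle(s) over core relations; "
            f"{len(members)} term(s) excluded from closure: "
            + ", ".join(sorted(members))
        )
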