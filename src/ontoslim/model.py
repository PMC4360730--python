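"""Core domain types shared across the toolkit.

The data model mirrors how genomics data-coordination portals annotate
experiment metadata with ontology terms: a vocabulary node
(:class:`OntologyTerm`), a typed edge between two nodes
(:class:`Relationship`), and the per-term derived bundle the portal serves
(:class:`TermIndexEntry` — ancestors, slim memberships per facet, search
strings).
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field

#: Relationship predicates with defined transitive-composition semantics.
#: ``is_a`` = subtype, ``part_of`` = part-whole containment, ``derives_from``
#: = temporal derivation inheriting a significant biological portion.
CORE_RELATIONS = frozenset({"is_a", "part_of", "derives_from"})

#: OBO synonym scopes.
SYNONYM_SCOPES = frozenset({"EXACT", "BROAD", "NARROW", "RELATED"})

CURIE_RE = re.compile(r"^[A-Za-z]+:[A-Za-z0-9_]+$")


def is_curie(value: str) -> bool:
    """True if *value* is a compact identifier like ``UBERON:0002107``."""
    return bool(CURIE_RE.match(value))


def namespace_of(curie: str) -> str:
    """Ontology prefix of a CURIE (``"UBERON"`` for ``"UBERON:0002107"``)."""
    return curie.split(":", 1)[0]


@dataclass(frozen=True)
class Synonym:
    """An alternative name attached to a term, with its OBO scope."""

    text: str
    scope: str = "RELATED"

    def __post_init__(self) -> None:
        if self.scope not in SYNONYM_SCOPES:
            raise ValueError(f"unknown synonym scope {self.scope!r}")


@dataclass
class OntologyTerm:
    """One controlled-vocabulary node.

    Parameters
    ----------
    id:
        CURIE identifier, e.g. ``"UBERON:0002107"``.
    name:
        Primary label, e.g. ``"liver"``.
    synonyms:
        Alternative names with OBO scopes (EXACT/BROAD/NARROW/RELATED).
    obsolete:
        Retired terms keep their node but lose outgoing edges at graph
        assembly; annotations to them are remapped via ``replaced_by``.
    replaced_by:
        Designated successor CURIE for an obsolete term, if any.
    xrefs:
        Cross-references to equivalent identifiers in other ontologies.
    """

    id: str
    name: str
    synonyms: list[Synonym] = field(default_factory=list)
    obsolete: bool = False
    replaced_by: str | None = None
    xrefs: list[str] = field(default_factory=list)
    consider: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not is_curie(self.id):
            raise ValueError(f"term id {self.id!r} is not a CURIE")

    @property
    def namespace(self) -> str:
        """Ontology prefix, the substring of ``id`` before the first colon."""
        return namespace_of(self.id)

    def synonym_texts(self) -> list[str]:
        return [s.text for s in self.synonyms]


@dataclass(frozen=True)
class Relationship:
    """A typed directed edge ``subject --predicate--> object``.

    ``predicate`` is one of the core labels (:data:`CORE_RELATIONS`) or any
    other label found in the source file (kept verbatim; such edges are
    stored but never contribute to closure or inference).
    """

    subject: str
    predicate: str
    object: str

    def __post_init__(self) -> None:
        if self.subject == self.object:
            raise ValueError(f"self-loop on {self.subject}")

    @property
    def is_core(self) -> bool:
        return self.predicate in CORE_RELATIONS


@dataclass
class TermIndexEntry:
    """Per-term derived bundle: the toolkit's primary output artifact.

    ``ancestors`` is the transitive closure over the core relations;
    ``slims`` maps each configured facet name to the slim members reachable
    from this term (always a subset of ``ancestors | {id}``).
    """

    id: str
    name: str
    synonyms: list[str] = field(default_factory=list)
    ancestors: set[str] = field(default_factory=set)
    slims: dict[str, set[str]] = field(default_factory=dict)
    obsolete: bool = False
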