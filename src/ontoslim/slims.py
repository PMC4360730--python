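"""Slim sets and the derived term index.

A *slim* is a curated subset of ontology terms standing for broad
categories (major organs, assay categories, ...). "Slimming" maps a
specific annotated term up the graph to the slim members among its
ancestors: a hepatoma cell line slims to the liver, ChIP-seq slims to the
immunoprecipitation-assay category. Because ontologies are DAGs, a term may
reach several slim members along different upward paths; all of them are
returned, not just the first encountered.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError
from .graph import OntologyGraph
from .model import CORE_RELATIONS, TermIndexEntry


@dataclass(frozen=True)
class SlimSet:
    """A named facet defined by a subset of term identifiers.

    ``relations`` controls the upward traversal: an anatomical facet needs
    the full ``{is_a, part_of, derives_from}`` set so a cell line can reach
    its organ of origin across ontology boundaries, while a pure subsumption
    hierarchy (assay categories) uses ``{is_a}`` only.
    """

    facet_name: str
    members: frozenset[str]
    relations: frozenset[str] = CORE_RELATIONS

    def __post_init__(self) -> None:
        if not self.members:
            raise ConfigError(f"slim {self.facet_name!r} has no members")
        if not self.relations:
            raise ConfigError(f"slim {self.facet_name!r} has no relations")


def validate_slims(graph: OntologyGraph, slims: Iterable[SlimSet]) -> None:
    """Raise :class:`ConfigError` listing every slim member absent from the
    graph, and on duplicate facet names."""
    seen: set[str] = set()
    missing: list[str] = []
    for slim in slims:
        if slim.facet_name in seen:
            raise ConfigError(f"duplicate facet name {slim.facet_name!r}")
        seen.add(slim.facet_name)
        for member in sorted(slim.members):
            if member not in graph.terms:
                missing.append(f"{slim.facet_name}:{member}")
    if missing:
        raise ConfigError("slim members absent from graph: " + ", ".join(missing))


def compute_slims(graph: OntologyGraph, term_id: str, slim: SlimSet) -> set[str]:
    """Slim members reachable from *term_id* (itself included if a member).

    Equals ``(ancestors(term, slim.relations) | {term}) & slim.members``:
    the traversal collects *all* slim members on any upward path rather than
    stopping at the first match, so diamond topologies where one term sits
    under two slim members yield both.
    """
    reach = graph.ancestors(term_id, slim.relations)
    reach.add(term_id)
    return reach & slim.members


def build_term_index(
    graph: OntologyGraph, slims: Sequence[SlimSet]
) -> list[TermIndexEntry]:
    """One :class:`TermIndexEntry` per non-obsolete term, sorted by id.

    Each entry carries the term's core-relation ancestor closure and, per
    configured facet, the slim members it maps to. Obsolete terms receive no
    entry; annotations to them are expected to resolve via ``replaced_by``.
    """
    validate_slims(graph, slims)
    entries = []
    for tid in sorted(graph.terms):
        term = graph.terms[tid]
        if term.obsolete:
            continue
        entries.append(
            TermIndexEntry(
                id=tid,
                name=term.name,
                synonyms=term.synonym_texts(),
                ancestors=graph.ancestors(tid, CORE_RELATIONS),
                slims={s.facet_name: compute_slims(graph, tid, s) for s in slims},
                obsolete=False,
            )
        )
    return entries


class TermIndexLookup:
    """Random-access wrapper over a term index plus the obsolete-alias map.

    ``get(annotated_id)`` resolves an annotation the way the portal does:
    direct hit first, then one hop through ``replaced_by``.
    """

    def __init__(
        self,
        entries: Iterable[TermIndexEntry],
        aliases: Mapping[str, str] | None = None,
    ):
        self.entries = list(entries)
        self.by_id = {e.id: e for e in self.entries}
        self.aliases = dict(aliases or {})

    @classmethod
    def from_graph(
        cls, graph: OntologyGraph, slims: Sequence[SlimSet]
    ) -> "TermIndexLookup":
        return cls(build_term_index(graph, slims), graph.aliases)

    def get(self, term_id: str | None) -> TermIndexEntry | None:
        if term_id is None:
            return None
        entry = self.by_id.get(term_id)
        if entry is None:
            replacement = self.aliases.get(term_id)
            if replacement is not None:
                entry = self.by_id.get(replacement)
        return entry

    def __contains__(self, term_id: str) -> bool:
        return self.get(term_id) is not None

    def __len__(self) -> int:
        return len(self.entries)


def load_slim_config(source: str | Path | IO[str]) -> list[SlimSet]:
    """Load slim definitions from a YAML/JSON document.

    Expected shape::

        slims:
          organ:
            relations: [is_a, part_of, derives_from]
            members: [UBERON:0002107, UBERON:0000955, UBERON:0000948]
          assay_category:
            relations: [is_a]
            members: [OBI:0000690]
    """
    if isinstance(source, (str, Path)):
        text = Path(source).read_text()
    else:
        text = source.read()
    doc = yaml.safe_load(text) or {}
    raw = doc.get("slims", doc)
    if not isinstance(raw, dict):
        raise ConfigError("slim configuration must map facet names to definitions")
    out = []
    for facet_name, spec in raw.items():
        if not isinstance(spec, dict) or "members" not in spec:
            raise ConfigError(f"slim {facet_name!r} needs a 'members' list")
        out.append(
            SlimSet(
                facet_name=str(facet_name),
                members=frozenset(spec["members"]),
                relations=frozenset(spec.get("relations", sorted(CORE_RELATIONS))),
            )
        )
    return out


def dump_slim_config(slims: Sequence[SlimSet], sink: IO[str]) -> None:
    doc = {
        "slims": {
            s.facet_name: {
                "relations": sorted(s.relations),
                "members": sorted(s.members),
            }
            for s in slims
        }
    }
    yaml.safe_dump(doc, sink, sort_keys=True)
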