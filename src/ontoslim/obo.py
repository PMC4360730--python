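"""OBO flat-file I/O and multi-ontology merging.

Supports the OBO 1.2/1.4 tag subset that ontology-backed metadata portals
actually need: ``id``, ``name``, ``synonym``, ``is_a``, ``relationship``,
``is_obsolete``, ``replaced_by``, ``xref``, ``consider``. Trailing ``!``
comments are stripped; unknown tags are ignored without error.

Also serialises the derived term index (see :mod:`ontoslim.slims`) as a
deterministic JSON document: keys sorted, set members sorted, so identical
inputs produce byte-identical files.
"""

from __future__ import annotations

import json
import re
from typing import IO, Iterable, TextIO

from .errors import OboParseError
from .graph import OntologyGraph
from .model import OntologyTerm, Relationship, Synonym, TermIndexEntry, is_curie

_STANZA_RE = re.compile(r"^\[([A-Za-z_-]+)\]\s*$")
_SYNONYM_RE = re.compile(
    r'^"((?:[^"\\]|\\.)*)"\s*(EXACT|BROAD|NARROW|RELATED)?\s*(?:\[[^\]]*\])?'
)


def _strip_comment(value: str) -> str:
    # An unescaped, unquoted "!" starts a trailing comment.
    out = []
    quoted = False
    prev = ""
    for ch in value:
        if ch == '"' and prev != "\\":
            quoted = not quoted
        elif ch == "!" and not quoted:
            break
        out.append(ch)
        prev = ch
    return "".join(out).strip()


def parse_obo(stream: Iterable[str]) -> tuple[list[OntologyTerm], list[Relationship]]:
    """Parse an OBO text stream into terms and relationships.

    One :class:`OntologyTerm` per ``[Term]`` stanza; one
    :class:`Relationship` per ``is_a:`` line and per
    ``relationship: <predicate> <id>`` line. Stanzas of other types
    (``[Typedef]``, ...) are skipped.

    Raises
    ------
    OboParseError
        On a malformed stanza header or tag line (with its line number), or
        on a duplicate term id within the file (naming the id).
    """
    terms: list[OntologyTerm] = []
    rels: list[Relationship] = []
    seen: set[str] = set()

    in_term = False       # inside a [Term] stanza
    in_stanza = False     # inside any stanza (vs. the header section)
    cur: dict | None = None
    cur_line = 0

    def flush() -> None:
        nonlocal cur
        if cur is None:
            return
        if "id" not in cur:
            raise OboParseError("[Term] stanza without an id tag", cur_line)
        tid = cur["id"]
        if tid in seen:
            raise OboParseError(f"duplicate term id {tid!r}", cur_line)
        seen.add(tid)
        terms.append(
            OntologyTerm(
                id=tid,
                name=cur.get("name", tid),
                synonyms=cur.get("synonyms", []),
                obsolete=cur.get("obsolete", False),
                replaced_by=cur.get("replaced_by"),
                xrefs=cur.get("xrefs", []),
                consider=cur.get("consider", []),
            )
        )
        rels.extend(cur.get("rels", []))
        cur = None

    for lineno, raw in enumerate(stream, start=1):
        line = _strip_comment(raw.rstrip("\n"))
        if not line:
            continue
        if line.startswith("["):
            m = _STANZA_RE.match(line)
            if not m:
                raise OboParseError(f"malformed stanza header {line!r}", lineno)
            flush()
            in_stanza = True
            in_term = m.group(1) == "Term"
            if in_term:
                cur = {}
                cur_line = lineno
            continue
        if not in_stanza or not in_term:
            continue  # file header or non-Term stanza content
        if ":" not in line:
            raise OboParseError(f"tag line without a colon: {line!r}", lineno)
        tag, _, value = line.partition(":")
        tag, value = tag.strip(), value.strip()
        assert cur is not None
        try:
            _apply_tag(cur, tag, value, lineno)
        except OboParseError:
            raise
        except KeyError as exc:
            raise OboParseError(f"{tag} tag before the id tag", lineno) from exc
        except ValueError as exc:
            raise OboParseError(str(exc), lineno) from exc
    flush()
    return terms, rels


def _apply_tag(cur: dict, tag: str, value: str, lineno: int) -> None:
    if tag == "id":
        if not is_curie(value):
            raise OboParseError(f"id {value!r} is not a CURIE", lineno)
        cur["id"] = value
    elif tag == "name":
        cur["name"] = value
    elif tag == "synonym":
        m = _SYNONYM_RE.match(value)
        if not m:
            raise OboParseError(f"malformed synonym line: {value!r}", lineno)
        text = m.group(1).replace('\\"', '"')
        cur.setdefault("synonyms", []).append(Synonym(text, m.group(2) or "RELATED"))
    elif tag == "is_a":
        cur.setdefault("rels", []).append(
            Relationship(cur["id"], "is_a", value.split()[0])
        )
    elif tag == "relationship":
        parts = value.split()
        if len(parts) < 2:
            raise OboParseError(f"malformed relationship line: {value!r}", lineno)
        cur.setdefault("rels", []).append(
            Relationship(cur["id"], parts[0], parts[1])
        )
    elif tag == "is_obsolete":
        cur["obsolete"] = value.lower() == "true"
    elif tag == "replaced_by":
        cur["replaced_by"] = value.split()[0]
    elif tag == "xref":
        cur.setdefault("xrefs", []).append(value.split()[0])
    elif tag == "consider":
        cur.setdefault("consider", []).append(value.split()[0])
    # unknown tags ignored


def merge_ontologies(
    parts: Iterable[tuple[list[OntologyTerm], list[Relationship]]],
    cycle_policy: str = "error",
) -> OntologyGraph:
    """Merge parsed ontology parts into one :class:`OntologyGraph`.

    A term id appearing in multiple parts keeps its first definition
    (first-wins on name/flags) with the union of synonyms, xrefs and edges;
    a conflicting name is recorded as a merge warning. Edges whose object is
    defined in no part are kept on the graph's ``dangling`` list. Outgoing
    edges of obsolete terms are dropped, and each obsolete term with a
    ``replaced_by`` contributes to the graph's alias map.

    ``cycle_policy`` is ``"error"`` (raise :class:`~ontoslim.errors.CycleError`
    on any core-relation cycle) or ``"warn"`` (exclude cyclic terms from
    closure, with a warning).
    """
    parts = list(parts)
    graph = OntologyGraph()
    for terms, _ in parts:
        for term in terms:
            if term.id not in graph.terms:
                graph.add_term(
                    OntologyTerm(
                        id=term.id,
                        name=term.name,
                        synonyms=list(term.synonyms),
                        obsolete=term.obsolete,
                        replaced_by=term.replaced_by,
                        xrefs=list(term.xrefs),
                        consider=list(term.consider),
                    )
                )
            else:
                first = graph.terms[term.id]
                if term.name != first.name:
                    graph.warnings.append(
                        f"conflicting names for {term.id}: kept {first.name!r}, "
                        f"ignored {term.name!r}"
                    )
                for syn in term.synonyms:
                    if syn not in first.synonyms:
                        first.synonyms.append(syn)
                for xref in term.xrefs:
                    if xref not in first.xrefs:
                        first.xrefs.append(xref)
    n_dropped = 0
    for _, rels in parts:
        for rel in rels:
            subject = graph.terms.get(rel.subject)
            if subject is None:
                # edge declared for a term the file never defines; treat as
                # dangling on the subject side as well
                graph.dangling.append(rel)
                continue
            if subject.obsolete:
                n_dropped += 1
                continue
            graph.add_edge(rel)
    if n_dropped:
        graph.warnings.append(
            f"dropped {n_dropped} outgoing edge(s) of obsolete terms"
        )
    for term in graph.terms.values():
        if term.obsolete and term.replaced_by:
            graph.aliases.setdefault(term.id, term.replaced_by)
    graph.enforce_acyclic(cycle_policy)
    return graph


# ---------------------------------------------------------------------------
# term-index serialization

def _entry_to_doc(entry: TermIndexEntry) -> dict:
    return {
        "id": entry.id,
        "name": entry.name,
        "synonyms": sorted(entry.synonyms),
        "ancestors": sorted(entry.ancestors),
        "slims": {facet: sorted(ids) for facet, ids in entry.slims.items()},
        "obsolete": entry.obsolete,
    }


def write_term_index(entries: Iterable[TermIndexEntry], sink: IO[str]) -> None:
    """Serialise index entries as deterministic JSON (byte-identical for
    identical input: entries sorted by id, keys and set members sorted)."""
    doc = {
        "format": "ontoslim-term-index",
        "version": 1,
        "terms": [_entry_to_doc(e) for e in sorted(entries, key=lambda e: e.id)],
    }
    json.dump(doc, sink, indent=1, sort_keys=True)
    sink.write("\n")


def read_term_index(stream: TextIO) -> list[TermIndexEntry]:
    """Read back a document written by :func:`write_term_index`."""
    doc = json.load(stream)
    if doc.get("format") != "ontoslim-term-index":
        raise ValueError("not an ontoslim term-index document")
    return [
        TermIndexEntry(
            id=t["id"],
            name=t["name"],
            synonyms=list(t["synonyms"]),
            ancestors=set(t["ancestors"]),
            slims={facet: set(ids) for facet, ids in t["slims"].items()},
            obsolete=bool(t.get("obsolete", False)),
        )
        for t in doc["terms"]
    ]


def write_obo(
    terms: Iterable[OntologyTerm],
    relationships: Iterable[Relationship],
    sink: IO[str],
    ontology_name: str = "ontoslim-fixture",
) -> None:
    """Write terms and relationships as an OBO 1.2 flat file.

    Round-trips through :func:`parse_obo` on ids, names, synonym texts and
    edges.
    """
    by_subject: dict[str, list[Relationship]] = {}
    for rel in relationships:
        by_subject.setdefault(rel.subject, []).append(rel)
    sink.write("format-version: 1.2\n")
    sink.write(f"ontology: {ontology_name}\n")
    for term in terms:
        sink.write(f"\n[Term]\nid: {term.id}\nname: {term.name}\n")
        for syn in term.synonyms:
            escaped = syn.text.replace('"', '\\"')
            sink.write(f'synonym: "{escaped}" {syn.scope} []\n')
        for xref in term.xrefs:
            sink.write(f"xref: {xref}\n")
        if term.obsolete:
            sink.write("is_obsolete: true\n")
        if term.replaced_by:
            sink.write(f"replaced_by: {term.replaced_by}\n")
        for cid in term.consider:
            sink.write(f"consider: {cid}\n")
        for rel in by_subject.get(term.id, []):
            if rel.predicate == "is_a":
                sink.write(f"is_a: {rel.object}\n")
            else:
                sink.write(f"relationship: {rel.predicate} {rel.object}\n")
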