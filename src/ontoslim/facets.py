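"""Annotation records, facet counting and facet filtering.

An :class:`AnnotationRecord` is one experiment's metadata document: the
assay performed, the biological sample it ran on (with its curated
biosample type), treatments applied, and bookkeeping fields. Facets are the
navigational filters a data portal shows next to search results. Two kinds
exist:

* *slim* facets are ontology-backed — a record is counted under every slim
  member its annotated term maps to (a Hep-G2 experiment shows up under the
  "liver" organ even though it is annotated to the cell line), and may be
  counted under several members when the DAG offers several upward paths;
* *literal* facets count raw field values (experiment status, available
  file formats).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

from .errors import ConfigError
from .slims import TermIndexLookup

#: The seven curated biosample types, each routed to designated ontologies
#: (see :mod:`ontoslim.validation`).
BIOSAMPLE_TYPES = (
    "tissue",
    "whole organism",
    "primary cell",
    "immortalized cell line",
    "in vitro differentiated cell",
    "induced pluripotent stem cell",
    "stem cell",
)

#: Bucket labels for records that cannot be placed under an ontology term.
UNANNOTATED = "unannotated"
NOT_IN_ONTOLOGY = "not in ontology"


@dataclass
class AnnotationRecord:
    """One experiment metadata document carrying term annotations."""

    record_id: str
    assay_term: str | None = None
    biosample_term: str | None = None
    biosample_type: str | None = None
    treatment_terms: list[str] = field(default_factory=list)
    antibody: str | None = None
    status: str = "released"
    available_data: list[str] = field(default_factory=list)
    organism: str | None = None

    def __post_init__(self) -> None:
        if self.biosample_type is not None and self.biosample_type not in BIOSAMPLE_TYPES:
            raise ValueError(
                f"{self.record_id}: biosample_type {self.biosample_type!r} is not "
                f"one of the {len(BIOSAMPLE_TYPES)} curated types"
            )


@dataclass(frozen=True)
class FacetDef:
    """How one facet is computed from a record.

    ``source="slim"`` reads the CURIE in ``field`` and expands it through
    the term index's slim mapping of the same facet name; ``source="literal"``
    counts the field value(s) directly.
    """

    name: str
    source: str  # "slim" | "literal"
    field: str   # record attribute: biosample_term, assay_term, status, ...

    def __post_init__(self) -> None:
        if self.source not in ("slim", "literal"):
            raise ConfigError(f"facet {self.name!r}: unknown source {self.source!r}")


@dataclass
class FacetCounts:
    """Counts for one facet; keys are CURIEs or literal values. The sum may
    exceed the record count because a record can slim to several members."""

    facet_name: str
    counts: dict[str, int] = field(default_factory=dict)


def _facet_values(record: AnnotationRecord, facet: FacetDef, index: TermIndexLookup) -> set[str]:
    """The facet values one record contributes to (may be empty)."""
    raw = getattr(record, facet.field)
    if facet.source == "literal":
        if raw is None:
            return {UNANNOTATED}
        if isinstance(raw, (list, tuple)):
            return set(raw) or {UNANNOTATED}
        return {str(raw)}
    # slim facet
    term_ids = raw if isinstance(raw, (list, tuple)) else [raw]
    term_ids = [t for t in term_ids if t is not None]
    if not term_ids:
        return {UNANNOTATED}
    values: set[str] = set()
    for tid in term_ids:
        entry = index.get(tid)
        if entry is None:
            values.add(NOT_IN_ONTOLOGY)
        else:
            values |= entry.slims.get(facet.name, set())
    return values


def compute_facets(
    records: Sequence[AnnotationRecord],
    index: TermIndexLookup | Iterable,
    facet_defs: Sequence[FacetDef],
) -> list[FacetCounts]:
    """Facet tables over a record corpus.

    For slim facets a record increments the count of *every* slim member its
    annotation maps to; records with no annotation land under
    ``"unannotated"`` and records annotated to ids the index does not cover
    under ``"not in ontology"``.
    """
    index = _as_lookup(index)
    out = []
    for facet in facet_defs:
        counts: dict[str, int] = {}
        for record in records:
            for value in _facet_values(record, facet, index):
                counts[value] = counts.get(value, 0) + 1
        out.append(FacetCounts(facet.name, dict(sorted(counts.items()))))
    return out


def filter_records(
    records: Sequence[AnnotationRecord],
    index: TermIndexLookup | Iterable,
    facet_defs: Sequence[FacetDef],
    selections: Mapping[str, str],
) -> list[AnnotationRecord]:
    """Conjunctive facet filtering.

    A record passes one selection when the selected value is among the
    values that record contributes to that facet (for slim facets: any of
    its slim members equals the selection); it must pass every selection.
    Empty selections return the corpus unchanged.
    """
    index = _as_lookup(index)
    defs = {f.name: f for f in facet_defs}
    for name in selections:
        if name not in defs:
            raise ConfigError(f"unknown facet {name!r}")
    out = []
    for record in records:
        if all(
            value in _facet_values(record, defs[name], index)
            for name, value in selections.items()
        ):
            out.append(record)
    return out


def _as_lookup(index) -> TermIndexLookup:
    return index if isinstance(index, TermIndexLookup) else TermIndexLookup(index)


# ---------------------------------------------------------------------------
# record corpus I/O (JSON array of documents)

_RECORD_FIELDS = (
    "record_id", "assay_term", "biosample_term", "biosample_type",
    "treatment_terms", "antibody", "status", "available_data", "organism",
)


def load_records(source: str | Path | IO[str]) -> list[AnnotationRecord]:
    """Load a record corpus from a JSON array; duplicate ids are an error."""
    if isinstance(source, (str, Path)):
        docs = json.loads(Path(source).read_text())
    else:
        docs = json.load(source)
    records = []
    seen: set[str] = set()
    for doc in docs:
        unknown = set(doc) - set(_RECORD_FIELDS)
        if unknown:
            raise ValueError(f"unknown record fields: {sorted(unknown)}")
        record = AnnotationRecord(**doc)
        if record.record_id in seen:
            raise ValueError(f"duplicate record_id {record.record_id!r}")
        seen.add(record.record_id)
        records.append(record)
    return records


def dump_records(records: Sequence[AnnotationRecord], sink: IO[str]) -> None:
    json.dump([asdict(r) for r in records], sink, indent=1, sort_keys=True)
    sink.write("\n")


def load_facet_defs(source: str | Path | IO[str]) -> list[FacetDef]:
    """Load facet definitions from YAML/JSON: a list of
    ``{name, source, field}`` mappings under the ``facets`` key."""
    import yaml

    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    doc = yaml.safe_load(text) or {}
    raw = doc.get("facets", doc)
    if not isinstance(raw, list):
        raise ConfigError("facet configuration must be a list of definitions")
    return [FacetDef(d["name"], d["source"], d["field"]) for d in raw]
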