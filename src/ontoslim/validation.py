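"""Ontology-driven metadata integrity checks.

Once experiment metadata is annotated with ontology terms, the ontology
itself becomes a validation instrument: annotated ids must exist and be
current, each curated biosample type routes to designated ontologies
(tissue -> anatomy ontology, immortalized line -> experimental-factor
ontology, ...), and slim membership can make other fields mandatory — the
canonical case being assays that slim to the immunoprecipitation-assay
category (ChIP-seq, iCLIP, ChIA-PET) requiring an antibody in the
metadata.

Rules are declarative data (:class:`ValidationRule`), so new curation
checks can be added through configuration; violations are data too, never
exceptions.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Mapping, Sequence

import yaml

from .errors import ConfigError
from .facets import AnnotationRecord
from .graph import OntologyGraph
from .model import namespace_of
from .slims import TermIndexLookup

#: Allowed ontology prefixes per curated biosample type. Stem cells may sit
#: in the cell ontology (physiological cell types) or, as established stem
#: cell lines, in the experimental-factor ontology; in vitro differentiated
#: cells are annotated to their intended product, hence either ontology.
ROUTING: dict[str, frozenset[str]] = {
    "tissue": frozenset({"UBERON"}),
    "whole organism": frozenset({"UBERON"}),
    "primary cell": frozenset({"CL"}),
    "stem cell": frozenset({"CL", "EFO"}),
    "immortalized cell line": frozenset({"EFO"}),
    "induced pluripotent stem cell": frozenset({"EFO"}),
    "in vitro differentiated cell": frozenset({"CL", "EFO"}),
}

RULE_KINDS = frozenset(
    {
        "term_exists",
        "not_obsolete",
        "namespace_routing",
        "required_field_when_slim",
        "namespace_reachable",
    }
)

#: Record fields holding term annotations, by metadata category.
TERM_FIELDS: dict[str, str] = {
    "biosample": "biosample_term",
    "assay": "assay_term",
    "treatment": "treatment_terms",
}


@dataclass(frozen=True)
class ValidationRule:
    """One declarative integrity rule.

    Parameters by kind:

    * ``term_exists`` / ``not_obsolete`` — optional ``fields`` (record
      attribute names; default: all three term-bearing fields).
    * ``namespace_routing`` — none (uses :data:`ROUTING`).
    * ``required_field_when_slim`` — ``facet`` (slim facet name),
      ``trigger`` (slim member CURIE), ``field`` (required record
      attribute), and the term field examined (``term_field``, default
      ``assay_term``).
    * ``namespace_reachable`` — ``namespace`` (target prefix, e.g.
      ``UBERON``) and ``term_field``; warns when an annotated term has no
      ancestor in that namespace (a missing cross-ontology bridge).
    """

    rule_id: str
    kind: str
    parameters: Mapping[str, object] = field(default_factory=dict)
    severity: str = "error"

    def __post_init__(self) -> None:
        if self.kind not in RULE_KINDS:
            raise ConfigError(f"rule {self.rule_id!r}: unknown kind {self.kind!r}")
        if self.severity not in ("error", "warning"):
            raise ConfigError(f"rule {self.rule_id!r}: bad severity {self.severity!r}")
        required = {
            "required_field_when_slim": {"facet", "trigger", "field"},
            "namespace_reachable": {"namespace"},
        }.get(self.kind, set())
        missing = required - set(self.parameters)
        if missing:
            raise ConfigError(
                f"rule {self.rule_id!r}: missing parameters {sorted(missing)}"
            )


@dataclass(frozen=True)
class Violation:
    """One integrity finding for one record."""

    record_id: str
    rule_id: str
    message: str
    offending_value: str | None = None
    severity: str = "error"


def _annotated_terms(record: AnnotationRecord, fields: Iterable[str]) -> list[tuple[str, str]]:
    out = []
    for f in fields:
        value = getattr(record, f)
        if value is None:
            continue
        if isinstance(value, (list, tuple)):
            out.extend((f, v) for v in value)
        else:
            out.append((f, value))
    return out


def check_routing(record: AnnotationRecord) -> list[Violation]:
    """Biosample-type -> ontology routing check for one record.

    A violation is produced iff the biosample term's namespace prefix is not
    allowed for the record's biosample type. Records lacking either field
    produce nothing here (other rules cover existence).
    """
    if record.biosample_type is None or record.biosample_term is None:
        return []
    allowed = ROUTING.get(record.biosample_type)
    if allowed is None:
        return [
            Violation(
                record.record_id,
                "routing",
                f"unknown biosample_type {record.biosample_type!r}",
                record.biosample_type,
            )
        ]
    ns = namespace_of(record.biosample_term)
    if ns not in allowed:
        return [
            Violation(
                record.record_id,
                "routing",
                f"biosample_type {record.biosample_type!r} must be annotated to "
                f"{{{', '.join(sorted(allowed))}}}, got {ns} "
                f"({record.biosample_term})",
                record.biosample_term,
            )
        ]
    return []


def _check_rule(
    record: AnnotationRecord,
    rule: ValidationRule,
    graph: OntologyGraph,
    index: TermIndexLookup,
) -> list[Violation]:
    p = rule.parameters
    if rule.kind == "term_exists":
        fields = p.get("fields", list(TERM_FIELDS.values()))
        return [
            Violation(
                record.record_id,
                rule.rule_id,
                f"{f}: term {tid} not found in the ontology graph",
                tid,
                rule.severity,
            )
            for f, tid in _annotated_terms(record, fields)
            if tid not in graph.terms and graph.resolve(tid)[0] is None
        ]
    if rule.kind == "not_obsolete":
        fields = p.get("fields", list(TERM_FIELDS.values()))
        out = []
        for f, tid in _annotated_terms(record, fields):
            term = graph.terms.get(tid)
            if term is None or not term.obsolete:
                continue
            resolved, remapped = graph.resolve(tid)
            if remapped:
                out.append(
                    Violation(
                        record.record_id,
                        rule.rule_id,
                        f"{f}: term {tid} is obsolete; remapped to {resolved}",
                        tid,
                        "warning",
                    )
                )
            else:
                out.append(
                    Violation(
                        record.record_id,
                        rule.rule_id,
                        f"{f}: term {tid} is obsolete with no replacement",
                        tid,
                        rule.severity,
                    )
                )
        return out
    if rule.kind == "namespace_routing":
        return [
            Violation(v.record_id, rule.rule_id, v.message, v.offending_value, rule.severity)
            for v in check_routing(record)
        ]
    if rule.kind == "required_field_when_slim":
        term_field = p.get("term_field", "assay_term")
        tid = getattr(record, term_field)
        entry = index.get(tid) if tid else None
        if entry is None:
            return []
        if p["trigger"] in entry.slims.get(p["facet"], set()):
            value = getattr(record, p["field"], None)
            if value in (None, "", [], ()):
                return [
                    Violation(
                        record.record_id,
                        rule.rule_id,
                        f"{term_field} {tid} slims to {p['trigger']} "
                        f"({p['facet']}) but {p['field']} is missing",
                        tid,
                        rule.severity,
                    )
                ]
        return []
    if rule.kind == "namespace_reachable":
        term_field = p.get("term_field", "biosample_term")
        tid = getattr(record, term_field)
        if tid is None:
            return []
        resolved, _ = graph.resolve(tid)
        if resolved is None:
            return []
        target = p["namespace"]
        if namespace_of(resolved) == target:
            return []
        if any(namespace_of(a) == target for a in graph.ancestors(resolved)):
            return []
        return [
            Violation(
                record.record_id,
                rule.rule_id,
                f"{term_field} {tid} has no path to any {target} ancestor "
                "(missing cross-ontology bridge)",
                tid,
                rule.severity,
            )
        ]
    raise AssertionError(f"unhandled rule kind {rule.kind}")  # pragma: no cover


def validate_record(
    record: AnnotationRecord,
    graph: OntologyGraph,
    index: TermIndexLookup,
    rules: Sequence[ValidationRule],
) -> list[Violation]:
    """Evaluate every rule against one record (no short-circuit).

    Pure and order-stable: violations come out grouped by rule in the order
    the rules were given.
    """
    out: list[Violation] = []
    for rule in rules:
        out.extend(_check_rule(record, rule, graph, index))
    return out


def validate_corpus(
    records: Sequence[AnnotationRecord],
    graph: OntologyGraph,
    index: TermIndexLookup,
    rules: Sequence[ValidationRule],
) -> list[Violation]:
    """:func:`validate_record` over a corpus, record order preserved."""
    out: list[Violation] = []
    for record in records:
        out.extend(validate_record(record, graph, index, rules))
    return out


def report_missing_terms(
    records: Sequence[AnnotationRecord], graph: OntologyGraph
) -> dict:
    """Summary of annotated ids absent from the graph, per category.

    Returns ``{"biosample"|"assay"|"treatment": {"count": n, "ids": [...]},
    "remapped": [(old, new), ...]}`` where ``count`` is the number of
    *distinct* unresolvable ids in that category and ``remapped`` lists
    obsolete ids that were auto-followed via ``replaced_by`` (resolved, but
    flagged). This is the working list for new-term requests to the upstream
    ontologies.
    """
    missing: dict[str, set[str]] = {cat: set() for cat in TERM_FIELDS}
    remapped: set[tuple[str, str]] = set()
    for record in records:
        for category, field_name in TERM_FIELDS.items():
            for _, tid in _annotated_terms(record, [field_name]):
                resolved, was_remapped = graph.resolve(tid)
                if resolved is None and tid not in graph.terms:
                    missing[category].add(tid)
                elif was_remapped:
                    remapped.add((tid, resolved))
    report: dict = {
        cat: {"count": len(ids), "ids": sorted(ids)} for cat, ids in missing.items()
    }
    report["remapped"] = sorted(remapped)
    return report


def default_rules() -> list[ValidationRule]:
    """The stock curation rule set.

    Existence and obsolescence checks on all annotated fields, biosample
    routing, the antibody-required rule for assays slimming to the
    immunoprecipitation-assay category, and the anatomy-bridging warning
    for biosample terms with no anatomy-ontology ancestor.
    """
    return [
        ValidationRule("term-exists", "term_exists"),
        ValidationRule("not-obsolete", "not_obsolete"),
        ValidationRule("biosample-routing", "namespace_routing"),
        ValidationRule(
            "antibody-required-for-ip",
            "required_field_when_slim",
            {
                "facet": "assay_category",
                "trigger": "OBI:0000690",
                "field": "antibody",
                "term_field": "assay_term",
            },
        ),
        ValidationRule(
            "uberon-bridge",
            "namespace_reachable",
            {"namespace": "UBERON", "term_field": "biosample_term"},
            severity="warning",
        ),
    ]


def load_rules(source: str | Path | IO[str]) -> list[ValidationRule]:
    """Load rules from YAML/JSON: a list of ``{rule_id, kind, parameters,
    severity}`` mappings under the ``rules`` key; duplicate ids rejected."""
    text = Path(source).read_text() if isinstance(source, (str, Path)) else source.read()
    doc = yaml.safe_load(text) or {}
    raw = doc.get("rules", doc)
    if not isinstance(raw, list):
        raise ConfigError("rule configuration must be a list of rules")
    rules = []
    seen: set[str] = set()
    for d in raw:
        rule = ValidationRule(
            rule_id=d["rule_id"],
            kind=d["kind"],
            parameters=d.get("parameters", {}),
            severity=d.get("severity", "error"),
        )
        if rule.rule_id in seen:
            raise ConfigError(f"duplicate rule_id {rule.rule_id!r}")
        seen.add(rule.rule_id)
        rules.append(rule)
    return rules


def dump_rules(rules: Sequence[ValidationRule], sink: IO[str]) -> None:
    doc = {
        "rules": [
            {
                "rule_id": r.rule_id,
                "kind": r.kind,
                "parameters": dict(r.parameters),
                "severity": r.severity,
            }
            for r in rules
        ]
    }
    yaml.safe_dump(doc, sink, sort_keys=False)
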