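# Methods

## Scope and data model

`ontoslim` implements the ontology layer a genomics metadata portal needs:
multi-ontology ingestion (OBO flat files), a merged typed-relation DAG with
closure and inference services, slim-based facet computation, synonym-
expanded search, and record validation. Terms are CURIE-identified nodes;
edges carry one of the core predicates `is_a` (subtype), `part_of`
(part–whole containment) or `derives_from` (temporal derivation that
inherits a significant biological portion), or any other label found in the
source file. Non-core labels are stored verbatim but never traversed: they
have no defined composition semantics here.

## OBO dialect

The parser supports the tag subset the machinery consumes: `id`, `name`,
`synonym` (with EXACT/BROAD/NARROW/RELATED scopes; unscoped synonyms
default to RELATED), `is_a`, `relationship`, `is_obsolete`, `replaced_by`,
`xref`, `consider`. Trailing `!` comments are stripped outside quoted
strings; unknown tags and non-`[Term]` stanzas are ignored without error.
Errors carry line numbers; a duplicate id within one file is an error
naming the id. A term stanza without a `name` keeps its id as the label
(some ontologies omit names on obsolete terms). OWL/RDF inputs and
description-logic reasoning are out of scope.

## Merge semantics

Merging is first-wins on a term's definition (name, obsolete flag) with
union of synonyms, xrefs and edges; a conflicting name is a logged warning,
not an error, because cross-ontology imports routinely re-declare terms.
Edges whose object no part defines are kept on a `dangling` list — they are
reported by validation but contribute no ancestors, since an unresolvable
id carries no knowledge. Obsolete terms keep their node (so annotations to
them can be diagnosed) but lose outgoing edges, and each `replaced_by`
populates an alias map; annotated ids are auto-followed through that map
exactly once and flagged as remapped.

Cycles over the core relations violate the DAG assumption. The default
policy is a hard error; a `warn` policy (for real-world snapshots that
occasionally ship cycles) records a warning and excludes the cyclic terms
from all closure computations rather than returning order-dependent
results.

## Closure and inferred relationships

`ancestors(t, R)` is reachability over edges whose predicate is in `R`,
computed on `networkx` subgraph views (the graph store is a
`MultiDiGraph` keyed by predicate, so parallel edges with distinct
predicates coexist). `roots(R)` are the non-obsolete terms without
resolvable outgoing `R`-edges; a term whose only parent edge is dangling
still counts as a root so that "every term reaches a root" holds on
imperfect inputs.

The label of an inferred relationship folds the composition table along a
path, left to right:

| first \ then  | is_a         | part_of      | derives_from |
|---------------|--------------|--------------|--------------|
| is_a          | is_a         | part_of      | derives_from |
| part_of       | part_of      | part_of      | derives_from |
| derives_from  | derives_from | derives_from | derives_from |

`is_a` is the identity on either side; `derives_from` dominates in either
order because once material descent enters a chain, further generalisation
or containment preserves it; `part_of ∘ part_of` is `part_of`. The
dominance of `derives_from` in the `part_of`-then-`derives_from` order is a
design choice of this package (only the mixed-with-`is_a` and
`derives_from`-then-generalisation cases are forced by the worked
cell-line example); it errs toward the weaker, still-true statement that
biological material is inherited. Among multiple shortest paths the
lexicographically smallest node sequence is folded, and parallel predicates
on one hop resolve in the order `is_a < part_of < derives_from` — both pure
determinism tie-breaks with no semantic weight.

## Slims and the term index

A slim is a named facet: a member set plus traversal relations.
`compute_slims(t, S) = (ancestors(t, S.relations) ∪ {t}) ∩ S.members` —
deliberately *collect-all* rather than stop-at-first-match, because a DAG
offers multiple upward paths and a term sitting under two configured organs
should surface under both; stop-at-first would silently drop facets on
diamond topologies. Facet-specific relation sets matter: an anatomical
facet needs all three core relations so a cell line can cross ontology
boundaries to its organ of origin, while an assay-category facet uses
`is_a` alone because assay ontologies are subsumption hierarchies and a
derivation edge should not leak categories.

The term index materialises, per non-obsolete term, its name, synonyms,
core-relation ancestor closure and per-facet slim members. Serialization is
deterministic (entries sorted by id, keys and set members sorted), so
rebuilding from unchanged inputs is byte-identical — this is load-bearing
for cache invalidation and is verified byte-for-byte in tests. JSON schemas
for the index and the record corpus ship under `src/ontoslim/schemas/`.

## Search

Text normalization is case-folding, punctuation stripping and whitespace
collapsing; no stemming and no fuzziness, so results are exactly
reproducible. Scores are a fixed monotone scheme — 1.0 exact full string,
0.8 whole token (or contiguous token run), 0.5 token substring — chosen for
testability; only the ordering is meaningful. All four synonym scopes are
searchable and scope does not affect the score. Record search returns a
record when any of its annotated terms (biosample, assay, treatments) is a
hit or has an ancestor that is a hit, which is how a child-term annotation
("lobe of liver") surfaces under a parent query ("liver").

## Validation

Rules are data (`ValidationRule` documents, loadable from YAML), evaluated
without short-circuiting into order-stable `Violation` lists; validation is
pure and removing a rule can only remove findings. Kinds: `term_exists`,
`not_obsolete` (remapped-via-`replaced_by` downgrades to a warning),
`namespace_routing`, `required_field_when_slim`, `namespace_reachable`.
The routing table sends tissue and whole-organism biosamples to UBERON,
primary cells to CL, immortalized and induced-pluripotent lines to EFO, and
allows both CL and EFO for stem cells (physiological stem-cell types live
in the cell ontology, established stem-cell lines in the experimental-
factor ontology) and for in vitro differentiated cells (annotated to their
intended product). `required_field_when_slim` fires iff the record's term
slims to the trigger member *and* the required field is empty — the stock
instance requires an antibody for assays slimming to the
immunoprecipitation-assay category. `namespace_reachable` is a warning that
a biosample term has no anatomy-ontology ancestor, i.e. a cross-ontology
bridge is missing; proposing the bridge itself is a curator's job and out
of scope.

## Synthetic data

The demo corpus is a hand-curated miniature: five single-namespace
branches (anatomy, cell types, cell lines, assays, chemicals) with the
cross-ontology edges that make the interesting behaviours reachable — the
cell-line → cell-type → organ chain, the breast / mammary-tissue synonym
pair, an immunoprecipitation branch over three assays, one obsolete term
with a `replaced_by`. Well-known terms use their real CURIEs for
readability; branch roots, a few assay ids and the obsolete term are
synthetic placeholders, and the graphs are stand-ins, not excerpts of any
ontology release. The six demo records instantiate the worked scenarios in
one corpus: two annotated methylation experiments, three
immunoprecipitation experiments of which exactly one lacks its antibody,
and the human/mouse pair for synonym search.

Random fixtures draw edges only from higher to lower topological index, so
they are acyclic by construction and deterministic per seed; record
annotations sample terms uniformly and do not respect the routing table
(they exercise mechanics, not curation policy). What these fixtures do
*not* emulate: real ontology scale (10⁴–10⁵ terms), real synonym richness
and cross-reference density, dialect quirks of specific OBO releases, and
realistic annotation skew. Passing tests therefore demonstrate correctness
of the graph algebra, the slimming semantics and the validation logic, not
performance or curation quality on production ontologies.

## Verification strategy and problem sizes

Every graph-algebra operation is checked against an independent naive
oracle operating on the raw pre-merge edge lists (breadth-first
reachability, DFS coloring for cycles, linear scans for search) across
seeded random DAG sweeps — 1000 graphs of 5–50 nodes in the acceptance
suite, with a third of them given a deliberate back-edge for the cycle
check — plus `hypothesis`-driven property tests for monotonicity,
containment and conjunctivity. The hand-written OBO parser is additionally
cross-checked against `obonet` on generated files. These sizes keep the
whole suite in a few seconds while saturating the branch structure of the
algorithms; the algorithms themselves are near-linear per query and scale
to real ontologies without modification.

## Known limitations

- The composition table is fixed; arbitrary OWL property chains are not
  expressible.
- Search has no ranking beyond the three-level match specificity, no
  stemming, and no fuzzy matching.
- Validation covers the rule kinds above; free-form cross-field constraint
  languages are out of scope.
- `merge_ontologies` is associative on term-id sets and edge sets but
  first-wins name resolution makes warning lists order-dependent (by
  design: the first-loaded ontology is authoritative).
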