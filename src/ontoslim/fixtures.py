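"""Synthetic miniature ontologies and record corpora.

Everything here is generated in memory — no ontology downloads. Two
families:

* :func:`demo_fixture` — a hand-curated miniature merge of anatomy (UBERON),
  cell-type (CL), experimental-factor (EFO), assay (OBI) and chemical
  (CHEBI) branches, wired exactly like the cross-ontology chains a genomics
  metadata portal relies on: a hepatoblastoma cell line that ``is_a``
  hepatoma cell line ``derives_from`` hepatocytes ``part_of`` the liver, the
  breast / "mammary tissue (synonym: lobe of breast)" search pair, and an
  immunoprecipitation assay branch over ChIP-seq / iCLIP / ChIA-PET. The
  CURIEs of well-known terms are the real ones (UBERON:0002107 liver, ...);
  branch roots and a few assay ids are synthetic placeholders, and the
  graphs are tiny synthetic stand-ins for the real ontologies, not excerpts
  of any release.
* :func:`random_fixture` — seeded random DAG + record corpora for
  property-based and oracle-equivalence testing; acyclic by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field

from .errors import ConfigError
from .facets import BIOSAMPLE_TYPES, AnnotationRecord, FacetDef
from .graph import OntologyGraph
from .model import CORE_RELATIONS, OntologyTerm, Relationship, Synonym
from .obo import merge_ontologies
from .slims import SlimSet

LIVER = "UBERON:0002107"
BRAIN = "UBERON:0000955"
HEART = "UBERON:0000948"
BREAST = "UBERON:0000310"
MAMMARY_TISSUE = "UBERON:0001911"
HEPATOCYTE = "CL:0000182"
HEPATIC_STELLATE = "CL:0000632"
B_CELL = "CL:0000236"
HEPATOMA_LINE = "EFO:0005216"
HEP_G2 = "EFO:0001187"
B_CELL_LINE = "EFO:0001640"
GM12878 = "EFO:0002784"
IP_ASSAY = "OBI:0000690"
CHIP_SEQ = "OBI:0000716"
ICLIP = "OBI:0002043"
CHIA_PET = "OBI:0001848"
METHYLATION_ASSAY = "OBI:0000634"
RRBS = "OBI:0001862"
MEDIP_SEQ = "OBI:0000693"
RNA_SEQ = "OBI:0001271"
HYDROXYECDYSONE = "CHEBI:16587"
ESTRADIOL = "CHEBI:23965"
#: Synthetic obsolete id demonstrating replaced_by remapping.
OBSOLETE_LIVER = "UBERON:9999901"


def _t(tid: str, name: str, *synonyms: tuple[str, str], **kw) -> OntologyTerm:
    return OntologyTerm(tid, name, synonyms=[Synonym(t, s) for t, s in synonyms], **kw)


def demo_obo_parts() -> dict[str, tuple[list[OntologyTerm], list[Relationship]]]:
    """The demo ontologies as separate per-ontology parts (pre-merge), keyed
    by ontology name — useful for exercising the merge step and for writing
    OBO files."""
    uberon_terms = [
        _t("UBERON:0001062", "anatomical entity"),
        _t("UBERON:0000062", "organ"),
        _t(LIVER, "liver"),
        _t(BRAIN, "brain"),
        _t(HEART, "heart"),
        _t(BREAST, "breast"),
        _t(MAMMARY_TISSUE, "mammary tissue", ("lobe of breast", "RELATED")),
        _t(OBSOLETE_LIVER, "obsolete hepatic structure", obsolete=True,
           replaced_by=LIVER),
    ]
    uberon_rels = [
        Relationship("UBERON:0000062", "is_a", "UBERON:0001062"),
        Relationship(LIVER, "is_a", "UBERON:0000062"),
        Relationship(BRAIN, "is_a", "UBERON:0000062"),
        Relationship(HEART, "is_a", "UBERON:0000062"),
        Relationship(BREAST, "is_a", "UBERON:0000062"),
        Relationship(MAMMARY_TISSUE, "part_of", BREAST),
    ]
    cl_terms = [
        _t("CL:0000000", "cell"),
        _t(HEPATOCYTE, "hepatocyte"),
        _t(HEPATIC_STELLATE, "hepatic stellate cell", ("Ito cell", "EXACT")),
        _t(B_CELL, "B cell", ("B lymphocyte", "EXACT")),
    ]
    cl_rels = [
        Relationship(HEPATOCYTE, "is_a", "CL:0000000"),
        Relationship(HEPATOCYTE, "part_of", LIVER),
        Relationship(HEPATIC_STELLATE, "is_a", "CL:0000000"),
        Relationship(HEPATIC_STELLATE, "part_of", LIVER),
        Relationship(B_CELL, "is_a", "CL:0000000"),
    ]
    efo_terms = [
        _t("EFO:0000322", "cell line"),
        _t(HEPATOMA_LINE, "hepatoma cell line"),
        _t(HEP_G2, "Hep-G2", ("HepG2", "EXACT")),
        _t(B_CELL_LINE, "B-cell derived cell line"),
        _t(GM12878, "GM12878"),
    ]
    efo_rels = [
        Relationship(HEPATOMA_LINE, "is_a", "EFO:0000322"),
        Relationship(HEPATOMA_LINE, "derives_from", HEPATOCYTE),
        Relationship(HEP_G2, "is_a", HEPATOMA_LINE),
        Relationship(B_CELL_LINE, "is_a", "EFO:0000322"),
        Relationship(B_CELL_LINE, "derives_from", B_CELL),
        Relationship(GM12878, "is_a", B_CELL_LINE),
    ]
    obi_terms = [
        _t("OBI:0000070", "assay"),
        _t(IP_ASSAY, "immunoprecipitation assay"),
        _t(CHIP_SEQ, "ChIP-seq", ("chromatin immunoprecipitation sequencing", "EXACT")),
        _t(ICLIP, "iCLIP"),
        _t(CHIA_PET, "ChIA-PET"),
        _t(METHYLATION_ASSAY, "DNA methylation profiling assay"),
        _t(RRBS, "RRBS", ("reduced representation bisulfite sequencing", "EXACT")),
        _t(MEDIP_SEQ, "MeDIP-seq"),
        _t(RNA_SEQ, "RNA-seq", ("transcription profiling by high throughput sequencing", "EXACT")),
    ]
    obi_rels = [
        Relationship(IP_ASSAY, "is_a", "OBI:0000070"),
        Relationship(CHIP_SEQ, "is_a", IP_ASSAY),
        Relationship(ICLIP, "is_a", IP_ASSAY),
        Relationship(CHIA_PET, "is_a", IP_ASSAY),
        Relationship(METHYLATION_ASSAY, "is_a", "OBI:0000070"),
        Relationship(RRBS, "is_a", METHYLATION_ASSAY),
        Relationship(MEDIP_SEQ, "is_a", METHYLATION_ASSAY),
        Relationship(RNA_SEQ, "is_a", "OBI:0000070"),
    ]
    chebi_terms = [
        _t("CHEBI:24431", "chemical entity"),
        _t(HYDROXYECDYSONE, "20-hydroxyecdysone"),
        _t(ESTRADIOL, "estradiol", ("oestradiol", "EXACT")),
    ]
    chebi_rels = [
        Relationship(HYDROXYECDYSONE, "is_a", "CHEBI:24431"),
        Relationship(ESTRADIOL, "is_a", "CHEBI:24431"),
    ]
    return {
        "uberon": (uberon_terms, uberon_rels),
        "cl": (cl_terms, cl_rels),
        "efo": (efo_terms, efo_rels),
        "obi": (obi_terms, obi_rels),
        "chebi": (chebi_terms, chebi_rels),
    }


def demo_slims() -> list[SlimSet]:
    """The organ slim (liver/brain/heart, full relation set) and the assay
    category slim (subsumption only)."""
    return [
        SlimSet("organ", frozenset({LIVER, BRAIN, HEART}), frozenset(CORE_RELATIONS)),
        SlimSet(
            "assay_category",
            frozenset({IP_ASSAY, METHYLATION_ASSAY}),
            frozenset({"is_a"}),
        ),
    ]


def demo_facet_defs() -> list[FacetDef]:
    return [
        FacetDef("organ", "slim", "biosample_term"),
        FacetDef("assay_category", "slim", "assay_term"),
        FacetDef("status", "literal", "status"),
        FacetDef("available_data", "literal", "available_data"),
    ]


def demo_records() -> list[AnnotationRecord]:
    """Six experiment records instantiating the worked scenarios at once.

    EXP001/EXP002 are the annotated-metadata pair (methylation assays on a
    treated primary cell and a treated immortalized line); EXP003-EXP005 are
    the three immunoprecipitation assays of which exactly EXP005 is missing
    its antibody; EXP005 (human breast tissue) and EXP006 (mouse mammary
    tissue) are the synonym-search pair.
    """
    return [
        AnnotationRecord(
            "EXP001",
            assay_term=RRBS,
            biosample_term=HEPATIC_STELLATE,
            biosample_type="primary cell",
            treatment_terms=[HYDROXYECDYSONE],
            organism="Homo sapiens",
            available_data=["fastq", "bed"],
        ),
        AnnotationRecord(
            "EXP002",
            assay_term=MEDIP_SEQ,
            biosample_term=HEP_G2,
            biosample_type="immortalized cell line",
            treatment_terms=[ESTRADIOL],
            organism="Homo sapiens",
            available_data=["fastq"],
        ),
        AnnotationRecord(
            "EXP003",
            assay_term=CHIP_SEQ,
            biosample_term=HEP_G2,
            biosample_type="immortalized cell line",
            antibody="H3K27ac",
            organism="Homo sapiens",
            available_data=["fastq", "bigWig"],
        ),
        AnnotationRecord(
            "EXP004",
            assay_term=ICLIP,
            biosample_term=GM12878,
            biosample_type="immortalized cell line",
            antibody="eIF4A3",
            organism="Homo sapiens",
            available_data=["fastq"],
        ),
        AnnotationRecord(
            "EXP005",
            assay_term=CHIA_PET,
            biosample_term=BREAST,
            biosample_type="tissue",
            antibody=None,  # the missing-antibody integrity case
            organism="Homo sapiens",
            available_data=["fastq"],
        ),
        AnnotationRecord(
            "EXP006",
            assay_term=RNA_SEQ,
            biosample_term=MAMMARY_TISSUE,
            biosample_type="tissue",
            organism="Mus musculus",
            available_data=["fastq", "tsv"],
        ),
    ]


def demo_fixture() -> tuple[OntologyGraph, list[SlimSet], list[AnnotationRecord]]:
    """The merged demo graph, its slim configuration and the 6-record corpus."""
    graph = merge_ontologies(demo_obo_parts().values())
    return graph, demo_slims(), demo_records()


# ---------------------------------------------------------------------------
# random fixtures

_DEFAULT_MIX = {"is_a": 0.6, "part_of": 0.3, "derives_from": 0.1}


@dataclass(frozen=True)
class FixtureSpec:
    """Parameters of a random ontology + corpus.

    ``edge_density`` is the probability of an edge between each ordered pair
    of terms (child -> parent only, so the result is acyclic by
    construction); ``relation_mix`` gives per-predicate probabilities and
    must sum to 1.
    """

    n_terms: int
    edge_density: float = 0.1
    relation_mix: dict = field(default_factory=lambda: dict(_DEFAULT_MIX))
    n_records: int = 0
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_terms < 1:
            raise ConfigError("n_terms must be >= 1")
        if not 0 < self.edge_density <= 1:
            raise ConfigError("edge_density must be in (0, 1]")
        if self.n_records < 0:
            raise ConfigError("n_records must be >= 0")
        total = sum(self.relation_mix.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"relation_mix must sum to 1 (got {total})")


def random_fixture(spec: FixtureSpec) -> tuple[OntologyGraph, list[AnnotationRecord]]:
    """Deterministic random DAG and record corpus for the given spec.

    Terms are ``RND:0000 .. RND:<n-1>``; an edge may run only from a
    higher-index term to a lower-index one, so the graph is acyclic and the
    low-index terms act as roots. Records annotate uniformly sampled terms
    as their biosample (type drawn uniformly over the seven categories; the
    routing check is intentionally not respected — random corpora exercise
    mechanics, not curation policy).
    """
    rng = random.Random(spec.seed)
    ids = [f"RND:{i:04d}" for i in range(spec.n_terms)]
    terms = [OntologyTerm(tid, f"random term {i}") for i, tid in enumerate(ids)]
    predicates = sorted(spec.relation_mix)
    weights = [spec.relation_mix[p] for p in predicates]
    rels = []
    for i in range(1, spec.n_terms):
        for j in range(i):
            if rng.random() < spec.edge_density:
                pred = rng.choices(predicates, weights=weights)[0]
                rels.append(Relationship(ids[i], pred, ids[j]))
    graph = merge_ontologies([(terms, rels)])
    records = [
        AnnotationRecord(
            f"REC{k:04d}",
            biosample_term=rng.choice(ids),
            biosample_type=rng.choice(BIOSAMPLE_TYPES),
            status=rng.choice(["released", "in progress"]),
        )
        for k in range(spec.n_records)
    ]
    return graph, records
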