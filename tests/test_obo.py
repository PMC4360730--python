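"""OBO parsing, multi-ontology merging and term-index serialization."""

from __future__ import annotations

import io

import pytest

from ontoslim import (
    OboParseError,
    OntologyTerm,
    Relationship,
    Synonym,
    TermIndexEntry,
    merge_ontologies,
    parse_obo,
    read_term_index,
    write_obo,
    write_term_index,
)
from ontoslim.fixtures import demo_obo_parts

LIVER_STANZA = """\
format-version: 1.2

[Term]
id: UBERON:0002107
name: liver
"""


def parse(text: str):
    return parse_obo(io.StringIO(text))


class TestParseObo:
    def test_minimal_term_stanza(self):
        terms, rels = parse(LIVER_STANZA)
        assert len(terms) == 1 and rels == []
        assert terms[0].id == "UBERON:0002107"
        assert terms[0].name == "liver"
        assert terms[0].namespace == "UBERON"

    def test_empty_stream(self):
        assert parse("") == ([], [])

    def test_synonym_scope_and_text(self):
        terms, _ = parse(
            "[Term]\nid: UBERON:0001911\nname: mammary tissue\n"
            'synonym: "lobe of breast" RELATED []\n'
            'synonym: "mammary gland" EXACT [FMA:1234]\n'
            'synonym: "unscoped alias"\n'
        )
        assert terms[0].synonyms == [
            Synonym("lobe of breast", "RELATED"),
            Synonym("mammary gland", "EXACT"),
            Synonym("unscoped alias", "RELATED"),  # scope defaults to RELATED
        ]

    def test_is_a_and_relationship_lines(self):
        _, rels = parse(
            "[Term]\nid: CL:0000182\nname: hepatocyte\n"
            "is_a: CL:0000000 ! cell\n"
            "relationship: part_of UBERON:0002107 ! liver\n"
        )
        assert rels == [
            Relationship("CL:0000182", "is_a", "CL:0000000"),
            Relationship("CL:0000182", "part_of", "UBERON:0002107"),
        ]

    def test_obsolete_and_replaced_by(self):
        terms, _ = parse(
            "[Term]\nid: UBERON:9999901\nname: old\nis_obsolete: true\n"
            "replaced_by: UBERON:0002107\n"
        )
        assert terms[0].obsolete is True
        assert terms[0].replaced_by == "UBERON:0002107"

    def test_unknown_tags_ignored(self):
        terms, _ = parse(
            "[Term]\nid: GO:0000001\nname: x\ndef: \"something\" []\n"
            "namespace: biological_process\ncreated_by: someone\n"
        )
        assert terms[0].name == "x"

    def test_non_term_stanzas_skipped(self):
        terms, rels = parse(
            "[Typedef]\nid: part_of\nname: part of\n" + LIVER_STANZA
        )
        assert [t.id for t in terms] == ["UBERON:0002107"]
        assert rels == []

    def test_comment_stripping_preserves_quoted_bang(self):
        terms, _ = parse(
            '[Term]\nid: X:1\nname: n\nsynonym: "loud! name" EXACT [] ! comment\n'
        )
        assert terms[0].synonyms[0].text == "loud! name"

    def test_malformed_stanza_header_reports_line(self):
        with pytest.raises(OboParseError, match="line 3"):
            parse("format-version: 1.2\n\n[Term\nid: X:1\n")

    def test_duplicate_id_reports_id(self):
        with pytest.raises(OboParseError, match="X:1"):
            parse("[Term]\nid: X:1\nname: a\n\n[Term]\nid: X:1\nname: b\n")

    def test_invalid_curie_rejected(self):
        with pytest.raises(OboParseError, match="line 2"):
            parse("[Term]\nid: not a curie\nname: x\n")

    def test_self_loop_rejected(self):
        with pytest.raises(OboParseError):
            parse("[Term]\nid: X:1\nname: x\nis_a: X:1\n")


class TestWriteObo:
    @pytest.mark.parametrize("part", sorted(demo_obo_parts()))
    def test_round_trip_identity(self, part):
        """parse(write(x)) preserves ids, names, synonyms and edges."""
        terms, rels = demo_obo_parts()[part]
        buf = io.StringIO()
        write_obo(terms, rels, buf)
        terms2, rels2 = parse(buf.getvalue())
        assert [(t.id, t.name, t.synonyms, t.obsolete, t.replaced_by) for t in terms] == [
            (t.id, t.name, t.synonyms, t.obsolete, t.replaced_by) for t in terms2
        ]
        assert sorted(rels, key=str) == sorted(rels2, key=str)

    def test_obonet_agrees_on_structure(self, tmp_path):
        """Cross-check the hand-written parser against obonet on the same file."""
        obonet = pytest.importorskip("obonet")
        terms, rels = demo_obo_parts()["uberon"]
        path = tmp_path / "uberon.obo"
        with path.open("w") as fh:
            write_obo(terms, rels, fh)
        g = obonet.read_obo(str(path))
        ours = {t.id: t for t in terms if not t.obsolete}
        # obonet drops obsolete terms by default, as our index does
        assert set(g.nodes) == set(ours)
        for tid in ours:
            assert g.nodes[tid]["name"] == ours[tid].name
        obonet_edges = {(u, v, k) for u, v, k in g.edges(keys=True)}
        our_edges = {(r.subject, r.object, r.predicate) for r in rels
                     if r.subject in ours}
        assert obonet_edges == our_edges


class TestMerge:
    def two_parts(self):
        a = (
            [OntologyTerm("A:1", "one"), OntologyTerm("A:2", "two"),
             OntologyTerm("A:3", "three")],
            [Relationship("A:2", "is_a", "A:1")],
        )
        b = (
            [OntologyTerm("B:1", "uno"), OntologyTerm("B:2", "dos")],
            [Relationship("B:2", "is_a", "B:1")],
        )
        return a, b

    def test_disjoint_union(self):
        a, b = self.two_parts()
        graph = merge_ontologies([a, b])
        assert len(graph) == 5
        assert graph.n_edges() == 2

    def test_merge_with_itself_is_idempotent(self):
        a, _ = self.two_parts()
        once = merge_ontologies([a])
        twice = merge_ontologies([a, a])
        assert set(once.terms) == set(twice.terms)
        assert sorted(once.edges(), key=str) == sorted(twice.edges(), key=str)
        assert [t.synonyms for t in once.terms.values()] == [
            t.synonyms for t in twice.terms.values()
        ]

    def test_associative_on_term_ids(self):
        a, b = self.two_parts()
        c = ([OntologyTerm("C:1", "c")], [])

        def as_part(graph):
            return list(graph.terms.values()), list(graph.edges())

        left = merge_ontologies([as_part(merge_ontologies([a, b])), c])
        right = merge_ontologies([a, as_part(merge_ontologies([b, c]))])
        flat = merge_ontologies([a, b, c])
        assert set(left.terms) == set(right.terms) == set(flat.terms)
        assert sorted(left.edges(), key=str) == sorted(flat.edges(), key=str)

    def test_dangling_edge_flagged_then_resolved_by_second_part(self):
        efo = (
            [OntologyTerm("EFO:0005216", "hepatoma cell line")],
            [Relationship("EFO:0005216", "derives_from", "CL:0000182")],
        )
        alone = merge_ontologies([efo])
        assert [r.object for r in alone.dangling] == ["CL:0000182"]
        cl = ([OntologyTerm("CL:0000182", "hepatocyte")], [])
        joined = merge_ontologies([efo, cl])
        assert joined.dangling == []
        assert joined.ancestors("EFO:0005216") == {"CL:0000182"}

    def test_first_definition_wins_with_warning(self):
        a = ([OntologyTerm("X:1", "alpha", synonyms=[Synonym("a", "EXACT")])], [])
        b = ([OntologyTerm("X:1", "beta", synonyms=[Synonym("b", "EXACT")])], [])
        graph = merge_ontologies([a, b])
        assert graph.terms["X:1"].name == "alpha"
        assert [s.text for s in graph.terms["X:1"].synonyms] == ["a", "b"]
        assert any("conflicting names" in w for w in graph.warnings)

    def test_obsolete_terms_lose_outgoing_edges(self):
        part = (
            [OntologyTerm("X:1", "old", obsolete=True, replaced_by="X:2"),
             OntologyTerm("X:2", "new")],
            [Relationship("X:1", "is_a", "X:2")],
        )
        graph = merge_ontologies([part])
        assert list(graph.out_edges("X:1")) == []
        assert graph.aliases == {"X:1": "X:2"}
        assert graph.resolve("X:1") == ("X:2", True)


class TestTermIndexIO:
    def entries(self):
        return [
            TermIndexEntry(
                id="EFO:0001187",
                name="Hep-G2",
                synonyms=["HepG2"],
                ancestors={"EFO:0005216", "CL:0000182", "UBERON:0002107"},
                slims={"organ": {"UBERON:0002107"}},
            ),
            TermIndexEntry(id="CL:0000182", name="hepatocyte"),
        ]

    def test_round_trip(self):
        buf = io.StringIO()
        write_term_index(self.entries(), buf)
        back = read_term_index(io.StringIO(buf.getvalue()))
        # order-insensitive equality (writer sorts by id)
        assert {e.id: (e.name, e.ancestors, e.slims) for e in back} == {
            e.id: (e.name, e.ancestors, e.slims) for e in self.entries()
        }

    def test_byte_identical_for_identical_input(self):
        bufs = []
        for _ in range(2):
            buf = io.StringIO()
            # set iteration order varies; serialization must not
            write_term_index(list(reversed(self.entries())), buf)
            bufs.append(buf.getvalue())
        assert bufs[0] == bufs[1]
        assert bufs[0].index("CL:0000182") < bufs[0].index("EFO:0001187")

    def test_empty_list(self):
        buf = io.StringIO()
        write_term_index([], buf)
        assert read_term_index(io.StringIO(buf.getvalue())) == []

    def test_document_contains_slim_ids(self):
        buf = io.StringIO()
        write_term_index(self.entries(), buf)
        assert "EFO:0001187" in buf.getvalue()
        assert "UBERON:0002107" in buf.getvalue()
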