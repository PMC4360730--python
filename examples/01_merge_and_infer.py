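"""Merge miniature ontologies and infer a cross-ontology relationship.

The demo corpus links an anatomy branch, a cell-type branch and a cell-line
branch. Following Hep-G2 upward: it is_a hepatoma cell line, which
derives_from hepatocytes, which are part_of the liver — so the toolkit can
infer that the cell line itself derives from hepatocytes (and, further,
from liver tissue)."""

from ontoslim import fixtures

graph, _, _ = fixtures.demo_fixture()

print(f"merged graph: {len(graph)} terms, {graph.n_edges()} edges, "
      f"{len(graph.dangling)} dangling, cycles={graph.detect_cycles()}")

anc = graph.ancestors(fixtures.HEP_G2)
print(f"ancestors of Hep-G2 ({fixtures.HEP_G2}): {sorted(anc)}")

for target in (fixtures.HEPATOCYTE, fixtures.LIVER):
    label = graph.infer_relationship(fixtures.HEP_G2, target)
    print(f"inferred: Hep-G2 --{label}--> {graph.terms[target].name} ({target})")

# The printed labels mean the cell line inherits biological material from
# hepatocytes / liver even though no single edge says so explicitly.
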