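"""Synonym-expanded free-text search across species naming differences.

Human samples are annotated to the term named "breast" while mouse samples
use "mammary tissue"; the latter carries the synonym "lobe of breast", so a
single query for "breast" returns experiments on both."""

from ontoslim import build_search_index, fixtures, search, search_records

graph, _, records = fixtures.demo_fixture()
index = build_search_index(graph)

for hit in search(index, "breast"):
    print(f"hit: {hit.term} via {hit.match_kind} "
          f"({hit.matched_text!r}, score {hit.score})")

matched = search_records(records, index, "breast")
for rid in matched:
    record = next(r for r in records if r.record_id == rid)
    print(f"experiment {rid}: {record.organism}, "
          f"biosample {record.biosample_term}")
# Both the human and the mouse experiment are returned from one query —
# the score marks how specific the match was (1.0 = exact name).
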