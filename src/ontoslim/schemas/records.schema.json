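{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ontoslim annotation record corpus",
 "type": "array",
 "items": {
  "type": "object",
  "required": ["record_id"],
  "additionalProperties": false,
  "properties": {
   "record_id": {"type": "string", "minLength": 1},
   "assay_term": {"type": ["string", "null"]},
   "biosample_term": {"type": ["string", "null"]},
   "biosample_type": {
    "type": ["string", "null"],
    "enum": [
     "tissue", "whole organism", "primary cell", "immortalized cell line",
     "in vitro differentiated cell", "induced pluripotent stem cell",
     "stem cell", null
    ]
   },
   "treatment_terms": {"type": "array", "items": {"type": "string"}},
   "antibody": {"type": ["string", "null"]},
   "status": {"type": "string"},
   "available_data": {"type": "array", "items": {"type": "string"}},
   "organism": {"type": ["string", "null"]}
  }
 }
}
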