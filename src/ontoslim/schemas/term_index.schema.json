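{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "ontoslim term index",
 "type": "object",
 "required": ["format", "version", "terms"],
 "properties": {
  "format": {"const": "ontoslim-term-index"},
  "version": {"const": 1},
  "terms": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["id", "name", "synonyms", "ancestors", "slims", "obsolete"],
    "properties": {
     "id": {"type": "string", "pattern": "^[A-Za-z]+:[A-Za-z0-9_]+$"},
     "name": {"type": "string", "minLength": 1},
     "synonyms": {"type": "array", "items": {"type": "string"}},
     "ancestors": {
      "type": "array",
      "items": {"type": "string", "pattern": "^[A-Za-z]+:[A-Za-z0-9_]+$"}
     },
     "slims": {
      "type": "object",
      "additionalProperties": {
       "type": "array",
       "items": {"type": "string", "pattern": "^[A-Za-z]+:[A-Za-z0-9_]+$"}
      }
     },
     "obsolete": {"type": "boolean"}
    }
   }
  }
 }
}
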