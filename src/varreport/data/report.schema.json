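{
 "$schema": "https://json-schema.org/draft/2020-12/schema",
 "title": "Annotated variant report",
 "type": "object",
 "required": ["subject", "variants"],
 "properties": {
  "subject": {"type": "string"},
  "glossary": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["term", "definition"],
    "properties": {
     "term": {"type": "string", "minLength": 1},
     "definition": {"type": "string"}
    }
   }
  },
  "variants": {
   "type": "array",
   "items": {
    "type": "object",
    "required": ["variant_id", "gene", "label", "zygosity", "frequency",
                 "impact", "evidence", "importance"],
    "properties": {
     "variant_id": {"type": "string", "minLength": 1},
     "gene": {"type": "string"},
     "label": {"type": "string"},
     "zygosity": {"enum": ["heterozygous", "homozygous", "unknown"]},
     "frequency": {"type": "number", "minimum": 0, "maximum": 1},
     "impact": {"enum": ["pathogenic", "benign", "protective"]},
     "evidence": {"enum": ["well-established", "likely", "uncertain"]},
     "importance": {"enum": ["low", "medium", "high"]},
     "conditions": {"type": "array", "items": {"type": "string"}},
     "summary": {"type": "string"},
     "links": {"type": "array", "items": {"type": "string"}}
    }
   }
  }
 }
}
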