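{
 "type": "object",
 "required": ["version", "seed", "config_hash", "stages"],
 "properties": {
  "version": {"type": "string"},
  "seed": {"type": "integer"},
  "config_hash": {"type": "string"},
  "stages": {
   "type": "object",
   "required": ["predict", "consensus", "enrich", "qsar"],
   "properties": {
    "predict": {
     "type": "object",
     "required": ["platforms", "n_predicted"],
     "properties": {
      "platforms": {"type": "array"},
      "n_predicted": {"type": "integer"}
     }
    },
    "consensus": {
     "type": "object",
     "required": ["union_size", "consensus_size", "consensus_targets"],
     "properties": {
      "union_size": {"type": "integer"},
      "consensus_size": {"type": "integer"},
      "consensus_targets": {"type": "array"}
     }
    },
    "enrich": {
     "type": "object",
     "required": ["n_tested", "n_selected", "selected_terms"],
     "properties": {
      "n_tested": {"type": "integer"},
      "n_selected": {"type": "integer"},
      "selected_terms": {"type": "array"}
     }
    },
    "qsar": {
     "type": "object",
     "required": ["n_molecules"],
     "properties": {
      "n_molecules": {"type": "integer"},
      "consensus_auc": {"type": "number"},
      "consensus_acc": {"type": "number"}
     }
    },
    "docking": {
     "type": "object",
     "required": ["n_rows"],
     "properties": {
      "n_rows": {"type": "integer"}
     }
    }
   }
  }
 }
}
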