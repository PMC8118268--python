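{
  "$schema": "https://json-schema.org/draft/2020-12/schema",
  "title": "pbdelim delimitation results",
  "type": "object",
  "required": ["sigma", "credibility_level", "partitions"],
  "properties": {
    "sigma": {"type": "number"},
    "credibility_level": {"type": "number"},
    "n_candidate_partitions": {"type": "integer"},
    "rate_estimate": {
      "type": "object",
      "required": ["sigma_hat", "log_likelihood", "boundary_flag"],
      "properties": {
        "sigma_hat": {"type": ["number", "null"]},
        "log_likelihood": {"type": "number"},
        "boundary_flag": {"type": "string"},
        "ci_low": {"type": ["number", "null"]},
        "ci_high": {"type": ["number", "null"]},
        "se": {"type": ["number", "null"]},
        "alpha": {"type": "number"},
        "ci_method": {"type": "string"},
        "ci_defined": {"type": "boolean"}
      }
    },
    "partitions": {
      "type": "array",
      "items": {
        "type": "object",
        "required": [
          "species_partition",
          "log_probability",
          "probability",
          "conditional_probability",
          "cumulative_conditional_probability",
          "in_credibility_set"
        ],
        "properties": {
          "species_partition": {
            "type": "array",
            "items": {"type": "array", "items": {"type": "string"}}
          },
          "n_species": {"type": "integer"},
          "log_probability": {"type": ["number", "null"]},
          "probability": {"type": "number"},
          "conditional_probability": {"type": "number"},
          "cumulative_conditional_probability": {"type": "number"},
          "in_credibility_set": {"type": "boolean"}
        }
      }
    }
  }
}
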