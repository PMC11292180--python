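# Extension schema for protist collections: extra environmental fields
# that supplement the core manifest for aquatic/cultured material.
name: dtol-protist
version: "1.0.0"
fields:
  - name: SALINITY
    requirement: OPTIONAL
    value_kind: DECIMAL
    visibility: PUBLIC
    term_mappings:
      mixs: salinity
  - name: WATER_TEMPERATURE
    requirement: OPTIONAL
    value_kind: DECIMAL
    visibility: PUBLIC
    term_mappings:
      mixs: temp
  - name: PH
    requirement: OPTIONAL
    value_kind: DECIMAL
    visibility: PUBLIC
    term_mappings:
      mixs: ph
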