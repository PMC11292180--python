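# Core sample-manifest schema, Tree of Life flavour.  One document per
# released version; field order here is the column order of the manifest.
name: dtol-core
version: "2.4.1"
fields:
  - name: SERIES
    requirement: OPTIONAL
    value_kind: INTEGER
    visibility: INTERNAL
  - name: RACK_OR_PLATE_ID
    requirement: MANDATORY
    value_kind: IDENTIFIER
    pattern: "^[A-Za-z0-9]+$"
    visibility: INTERNAL
  - name: TUBE_OR_WELL_ID
    requirement: MANDATORY
    value_kind: IDENTIFIER
    pattern: "^[A-Za-z0-9]+$"
    visibility: PUBLIC
    term_mappings:
      dwc: measurementID
      ena: tube or well id
  - name: SPECIMEN_ID
    requirement: MANDATORY
    value_kind: IDENTIFIER
    pattern: "^[A-Za-z0-9_]+$"
    visibility: PUBLIC
    term_mappings:
      dwc: materialSampleID
      ena: specimen id
  - name: ENV_SAMPLE_ID
    requirement: OPTIONAL
    value_kind: IDENTIFIER
    pattern: "^[A-Za-z0-9_]+$"
    visibility: PUBLIC
  - name: SCIENTIFIC_NAME
    requirement: MANDATORY
    value_kind: FREE_TEXT
    visibility: PUBLIC
    term_mappings:
      dwc: scientificName
      ena: SCIENTIFIC_NAME
  - name: TAXON_ID
    requirement: MANDATORY
    value_kind: INTEGER
    visibility: PUBLIC
    term_mappings:
      dwc: taxonID
      ena: TAXON_ID
  - name: ORGANISM_PART
    requirement: MANDATORY
    value_kind: CONTROLLED
    visibility: PUBLIC
    vocabulary:
      - WHOLE_ORGANISM
      - HEAD
      - THORAX
      - ABDOMEN
      - LEG
      - BLOOD
      - MUSCLE
      - LEAF
      - THALLUS
      - MYCELIUM
      - NOT_COLLECTED
    term_mappings:
      ena: organism part
  - name: SYMBIONT
    requirement: OPTIONAL
    value_kind: CONTROLLED
    visibility: PUBLIC
    vocabulary: [TARGET, SYMBIONT]
  - name: LIFESTAGE
    requirement: OPTIONAL
    value_kind: CONTROLLED
    visibility: PUBLIC
    vocabulary:
      - ADULT
      - JUVENILE
      - LARVA
      - EGG
      - SPORE_BEARING_STRUCTURE
      - NOT_COLLECTED
    term_mappings:
      dwc: lifeStage
      ena: lifestage
  - name: SEX
    requirement: MANDATORY
    value_kind: CONTROLLED
    visibility: PUBLIC
    vocabulary: [MALE, FEMALE, HERMAPHRODITE, UNKNOWN, NOT_COLLECTED]
    term_mappings:
      dwc: sex
      ena: sex
  - name: DATE_OF_COLLECTION
    requirement: MANDATORY
    value_kind: DATE
    visibility: PUBLIC
    term_mappings:
      dwc: verbatimEventDate
      ena: collection date
      mixs: collection_date
  - name: COLLECTION_LOCATION
    requirement: MANDATORY
    value_kind: FREE_TEXT
    visibility: PUBLIC
    term_mappings:
      dwc: locality
      ena: geographic location (region and locality)
      mixs: geo_loc_name
  - name: DECIMAL_LATITUDE
    requirement: MANDATORY
    value_kind: DECIMAL
    visibility: PUBLIC
    term_mappings:
      dwc: decimalLatitude
      ena: geographic location (latitude)
      mixs: lat_lon
  - name: DECIMAL_LONGITUDE
    requirement: MANDATORY
    value_kind: DECIMAL
    visibility: PUBLIC
    term_mappings:
      dwc: decimalLongitude
      ena: geographic location (longitude)
      mixs: lat_lon
  - name: COLLECTED_BY
    requirement: OPTIONAL
    value_kind: FREE_TEXT
    visibility: PUBLIC
    term_mappings:
      dwc: recordedBy
      ena: collected_by
  - name: COLLECTION_EVENT
    requirement: OPTIONAL
    value_kind: FREE_TEXT
    visibility: INTERNAL
    term_mappings:
      dwc: eventID
  - name: IDENTIFIED_BY
    requirement: OPTIONAL
    value_kind: FREE_TEXT
    visibility: PUBLIC
    term_mappings:
      dwc: identifiedBy
      ena: identified_by
  - name: IDENTIFICATION_UNCERTAINTY
    requirement: OPTIONAL
    value_kind: FREE_TEXT
    visibility: INTERNAL
  - name: HAZARD_GROUP
    requirement: OPTIONAL
    value_kind: CONTROLLED
    visibility: INTERNAL
    vocabulary: [HG1, HG2, HG3]
  - name: PRESERVATION_APPROACH
    requirement: OPTIONAL
    value_kind: CONTROLLED
    visibility: PUBLIC
    vocabulary:
      - SNAP_FROZEN
      - ETHANOL
      - DRY_ICE
      - OTHER
      - NOT_COLLECTED
  - name: VOUCHER_ID
    requirement: OPTIONAL
    value_kind: IDENTIFIER
    visibility: PUBLIC
    term_mappings:
      dwc: otherCatalogNumbers
  - name: REGULATORY_COMPLIANCE
    requirement: OPTIONAL
    value_kind: CONTROLLED
    visibility: INTERNAL
    vocabulary: ["Y", "N", NOT_APPLICABLE]
  - name: GAL
    requirement: MANDATORY
    value_kind: FREE_TEXT
    visibility: PUBLIC
    term_mappings:
      ena: GAL
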