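{
  "schema_version": "1.0",
  "description": "Data dictionary for patient-centered multimodal cohort records. One JSON object per patient; a cohort file is a JSON array of such objects. Missing values are encoded as null; an absent key is equivalent to null. All day counts are integers with day 0 = initial diagnosis.",
  "fields": [
    {"field": "patient_id", "type": "string", "possible_values": "zero-padded decimal string, unique within a cohort", "required": true},
    {"field": "sex", "type": "category", "possible_values": ["male", "female"], "required": true},
    {"field": "age_at_diagnosis", "type": "integer (years)", "possible_values": ">= 0", "required": true},
    {"field": "smoking_status", "type": "category", "possible_values": ["never", "former", "current", "unknown"], "required": true},
    {"field": "primary_site", "type": "category", "possible_values": ["oral_cavity", "oropharynx", "hypopharynx", "larynx", "cup"], "required": true},
    {"field": "grading", "type": "ordinal category", "possible_values": ["G1", "G2", "G3", "G4", null], "required": false, "note": "HPV-associated carcinoma is not graded; null means ungraded/unknown"},
    {"field": "pt_stage", "type": "ordinal category", "possible_values": ["pTis", "pT1", "pT2", "pT3", "pT4", "pT4a", "pT4b", null], "required": false},
    {"field": "pn_stage", "type": "ordinal category", "possible_values": ["pN0", "pN1", "pN2", "pN2a", "pN2b", "pN2c", "pN3", null], "required": false},
    {"field": "lymphatic_invasion", "type": "tri-state boolean", "possible_values": [true, false, null], "required": false},
    {"field": "vascular_invasion", "type": "tri-state boolean", "possible_values": [true, false, null], "required": false},
    {"field": "perineural_invasion", "type": "tri-state boolean", "possible_values": [true, false, null], "required": false},
    {"field": "carcinoma_in_situ", "type": "tri-state boolean", "possible_values": [true, false, null], "required": false},
    {"field": "hpv_positive", "type": "tri-state boolean", "possible_values": [true, false, null], "required": false},
    {"field": "resection_margin_positive", "type": "tri-state boolean", "possible_values": [true, false, null], "required": false},
    {"field": "blood", "type": "object", "possible_values": "map parameter-name -> {value: finite float, unit: string, group: string (e.g. hematology, clinical_chemistry, coagulation)}", "required": false},
    {"field": "icd_codes", "type": "list of strings", "possible_values": "ICD-10 code strings, e.g. \"C32.0\"", "required": false},
    {"field": "tma_density", "type": "object", "possible_values": "map over keys CD3_tumor_center, CD3_invasion_front, CD8_tumor_center, CD8_invasion_front -> cells per mm^2 (float >= 0) or null", "required": false},
    {"field": "recurrence_days", "type": "integer (days)", "possible_values": ">= 0 or null (no recurrence recorded)", "required": false},
    {"field": "death_days", "type": "integer (days)", "possible_values": ">= 0 or null (alive at end of follow-up); when present it defines the end of follow-up", "required": false},
    {"field": "death_tumor_specific", "type": "tri-state boolean", "possible_values": [true, false, null], "required": false, "note": "null = cause of death unknown"},
    {"field": "followup_days", "type": "integer (days)", "possible_values": ">= 0", "required": true}
  ]
}
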