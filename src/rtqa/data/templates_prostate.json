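{
  "disease_site": "PROSTATE",
  "version": "rtqa representative prostate templates v1",
  "templates": {
    "CONSULT": {
      "fields": [
        {"name": "consult_date", "type": "date", "required": true},
        {"name": "age", "type": "integer", "required": true, "range": [18, 110], "unit": "years"},
        {"name": "ecog_performance_status", "type": "integer", "required": true, "range": [0, 4], "vocab_source": "ECOG"},
        {"name": "t_stage", "type": "vocab", "required": true, "vocabulary": ["T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4"], "vocab_source": "AJCC 8th"},
        {"name": "n_stage", "type": "vocab", "required": true, "vocabulary": ["N0", "N1"], "vocab_source": "AJCC 8th"},
        {"name": "m_stage", "type": "vocab", "required": true, "vocabulary": ["M0", "M1a", "M1b", "M1c"], "vocab_source": "AJCC 8th"},
        {"name": "gleason_primary", "type": "integer", "required": true, "range": [3, 5]},
        {"name": "gleason_secondary", "type": "integer", "required": true, "range": [3, 5]},
        {"name": "psa", "type": "number", "required": true, "range": [0, 5000], "unit": "ng/mL"},
        {"name": "nccn_risk_group", "type": "vocab", "required": true, "vocabulary": ["LOW", "INTERMEDIATE", "HIGH"], "vocab_source": "NCCN"},
        {"name": "treatment_intent", "type": "vocab", "required": true, "vocabulary": ["CURATIVE", "PALLIATIVE"]},
        {"name": "prior_radiotherapy", "type": "boolean", "required": true},
        {"name": "hormone_therapy_planned", "type": "boolean", "required": false},
        {"name": "comorbidity", "type": "string", "required": false}
      ]
    },
    "SIM_DIRECTIVE": {
      "fields": [
        {"name": "sim_date", "type": "date", "required": true},
        {"name": "immobilization", "type": "vocab", "required": true, "vocabulary": ["VACUUM_BAG", "KNEE_FOOT_LOCK", "NONE"]},
        {"name": "ct_slice_thickness_mm", "type": "number", "required": true, "range": [0.5, 5.0], "unit": "mm"},
        {"name": "bladder_filling", "type": "vocab", "required": true, "vocabulary": ["FULL", "EMPTY", "COMFORTABLY_FULL"]},
        {"name": "rectal_preparation", "type": "vocab", "required": false, "vocabulary": ["EMPTY", "ENEMA", "NONE"]},
        {"name": "image_guidance", "type": "vocab", "required": true, "vocabulary": ["CBCT", "KV_PLANAR", "FIDUCIALS", "MRI"]}
      ]
    },
    "OTV": {
      "fields": [
        {"name": "otv_date", "type": "date", "required": true},
        {"name": "week_number", "type": "integer", "required": true, "range": [1, 12]},
        {"name": "toxicity_gu_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"},
        {"name": "toxicity_gi_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"},
        {"name": "weight_kg", "type": "number", "required": false, "range": [30, 250], "unit": "kg"}
      ]
    },
    "EOT": {
      "fields": [
        {"name": "eot_date", "type": "date", "required": true},
        {"name": "total_dose_gy", "type": "number", "required": true, "range": [0, 200], "unit": "Gy"},
        {"name": "fractions_delivered", "type": "integer", "required": true, "range": [1, 60]},
        {"name": "treatment_completed", "type": "boolean", "required": true},
        {"name": "t_stage", "type": "vocab", "required": true, "vocabulary": ["T1a", "T1b", "T1c", "T2a", "T2b", "T2c", "T3a", "T3b", "T4"], "vocab_source": "AJCC 8th"},
        {"name": "nccn_risk_group", "type": "vocab", "required": true, "vocabulary": ["LOW", "INTERMEDIATE", "HIGH"], "vocab_source": "NCCN"},
        {"name": "toxicity_gu_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"},
        {"name": "toxicity_gi_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"}
      ]
    },
    "FOLLOWUP": {
      "fields": [
        {"name": "followup_date", "type": "date", "required": true},
        {"name": "psa", "type": "number", "required": false, "range": [0, 5000], "unit": "ng/mL"},
        {"name": "disease_status", "type": "vocab", "required": true, "vocabulary": ["NED", "BIOCHEMICAL_RECURRENCE", "LOCAL_RECURRENCE", "DISTANT_PROGRESSION"]},
        {"name": "toxicity_gu_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"},
        {"name": "toxicity_gi_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"}
      ]
    }
  },
  "flows": {
    "EOT": [
      ["CONSULT", "t_stage", "t_stage"],
      ["CONSULT", "nccn_risk_group", "nccn_risk_group"]
    ]
  },
  "boilerplates": {
    "CONSULT": "Radiation oncology consult dated {consult_date}. The patient is a {age} year old man with ECOG performance status {ecog_performance_status}. Staging: {t_stage} {n_stage} {m_stage}. Gleason score {gleason_primary}+{gleason_secondary}. PSA was {psa} ng/mL. NCCN risk group: {nccn_risk_group}. Treatment intent is {treatment_intent}. Prior radiotherapy: {prior_radiotherapy}. Hormone therapy planned: {hormone_therapy_planned}. Comorbidity: {comorbidity}.",
    "EOT": "End of treatment summary dated {eot_date}. Delivered {total_dose_gy} Gy in {fractions_delivered} fractions. Treatment completed: {treatment_completed}. Stage at consult: {t_stage}. NCCN risk group: {nccn_risk_group}. GU toxicity grade {toxicity_gu_grade}, GI toxicity grade {toxicity_gi_grade}."
  }
}
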