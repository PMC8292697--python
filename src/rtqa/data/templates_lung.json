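{
  "disease_site": "LUNG",
  "version": "rtqa representative lung templates v1",
  "templates": {
    "CONSULT": {
      "fields": [
        {"name": "consult_date", "type": "date", "required": true},
        {"name": "age", "type": "integer", "required": true, "range": [18, 110], "unit": "years"},
        {"name": "ecog_performance_status", "type": "integer", "required": true, "range": [0, 4], "vocab_source": "ECOG"},
        {"name": "t_stage", "type": "vocab", "required": true, "vocabulary": ["T1a", "T1b", "T1c", "T2a", "T2b", "T3", "T4"], "vocab_source": "AJCC 8th"},
        {"name": "n_stage", "type": "vocab", "required": true, "vocabulary": ["N0", "N1", "N2", "N3"], "vocab_source": "AJCC 8th"},
        {"name": "m_stage", "type": "vocab", "required": true, "vocabulary": ["M0", "M1a", "M1b", "M1c"], "vocab_source": "AJCC 8th"},
        {"name": "histology", "type": "vocab", "required": true, "vocabulary": ["ADENOCARCINOMA", "SQUAMOUS", "SMALL_CELL", "NSCLC_NOS"]},
        {"name": "smoking_status", "type": "vocab", "required": true, "vocabulary": ["CURRENT", "FORMER", "NEVER"]},
        {"name": "fev1_pct_predicted", "type": "number", "required": false, "range": [10, 150], "unit": "%"},
        {"name": "treatment_intent", "type": "vocab", "required": true, "vocabulary": ["CURATIVE", "PALLIATIVE"]},
        {"name": "prior_radiotherapy", "type": "boolean", "required": true},
        {"name": "concurrent_chemotherapy_planned", "type": "boolean", "required": false}
      ]
    },
    "SIM_DIRECTIVE": {
      "fields": [
        {"name": "sim_date", "type": "date", "required": true},
        {"name": "motion_management", "type": "vocab", "required": true, "vocabulary": ["FOUR_D_CT", "BREATH_HOLD", "ABDOMINAL_COMPRESSION", "FREE_BREATHING"]},
        {"name": "immobilization", "type": "vocab", "required": true, "vocabulary": ["WING_BOARD", "VACUUM_BAG", "NONE"]},
        {"name": "ct_slice_thickness_mm", "type": "number", "required": true, "range": [0.5, 5.0], "unit": "mm"},
        {"name": "iv_contrast", "type": "boolean", "required": false}
      ]
    },
    "OTV": {
      "fields": [
        {"name": "otv_date", "type": "date", "required": true},
        {"name": "week_number", "type": "integer", "required": true, "range": [1, 12]},
        {"name": "toxicity_esophagitis_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"},
        {"name": "toxicity_pneumonitis_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"},
        {"name": "weight_kg", "type": "number", "required": false, "range": [30, 250], "unit": "kg"}
      ]
    },
    "EOT": {
      "fields": [
        {"name": "eot_date", "type": "date", "required": true},
        {"name": "total_dose_gy", "type": "number", "required": true, "range": [0, 200], "unit": "Gy"},
        {"name": "fractions_delivered", "type": "integer", "required": true, "range": [1, 60]},
        {"name": "treatment_completed", "type": "boolean", "required": true},
        {"name": "t_stage", "type": "vocab", "required": true, "vocabulary": ["T1a", "T1b", "T1c", "T2a", "T2b", "T3", "T4"], "vocab_source": "AJCC 8th"},
        {"name": "toxicity_esophagitis_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"},
        {"name": "toxicity_pneumonitis_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"}
      ]
    },
    "FOLLOWUP": {
      "fields": [
        {"name": "followup_date", "type": "date", "required": true},
        {"name": "disease_status", "type": "vocab", "required": true, "vocabulary": ["NED", "LOCAL_RECURRENCE", "REGIONAL_RECURRENCE", "DISTANT_PROGRESSION"]},
        {"name": "imaging_response", "type": "vocab", "required": false, "vocabulary": ["CR", "PR", "SD", "PD"], "vocab_source": "RECIST 1.1"},
        {"name": "toxicity_pneumonitis_grade", "type": "integer", "required": true, "range": [0, 5], "vocab_source": "CTCAE v5"}
      ]
    }
  },
  "flows": {
    "EOT": [
      ["CONSULT", "t_stage", "t_stage"]
    ]
  },
  "boilerplates": {
    "CONSULT": "Radiation oncology consult dated {consult_date}. The patient is {age} years old with ECOG performance status {ecog_performance_status}. Staging: {t_stage} {n_stage} {m_stage}. Histology: {histology}. Smoking status: {smoking_status}. FEV1 percent predicted: {fev1_pct_predicted}. Treatment intent is {treatment_intent}. Prior radiotherapy: {prior_radiotherapy}. Concurrent chemotherapy planned: {concurrent_chemotherapy_planned}.",
    "EOT": "End of treatment summary dated {eot_date}. Delivered {total_dose_gy} Gy in {fractions_delivered} fractions. Treatment completed: {treatment_completed}. Stage at consult: {t_stage}. Esophagitis grade {toxicity_esophagitis_grade}, pneumonitis grade {toxicity_pneumonitis_grade}."
  }
}
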