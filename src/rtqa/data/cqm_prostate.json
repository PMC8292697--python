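{
  "ruleset_id": "rtqa-prostate-example-v1",
  "comment": "Illustrative structural examples of decision-tree quality measures; not a transcription of any published measure set.",
  "feature_dictionary": [
    "record.disease_site",
    "record.consult.nccn_risk_group",
    "record.consult.treatment_intent",
    "record.consult.hormone_therapy_planned",
    "record.consult.prior_radiotherapy",
    "record.eot.treatment_completed",
    "record.eot.total_dose_gy",
    "record.eot.fractions_delivered",
    "plan.prescription_dose",
    "plan.fractions",
    "plan.dose_per_fraction",
    "dvh.plan_status",
    "dvh.Rectum.V70Gy.status",
    "dvh.Bladder.V70Gy.status"
  ],
  "measures": [
    {
      "measure_id": "PROS-ADT-HIGH",
      "title": "High-risk patients treated with curative intent have hormone therapy planned",
      "category": "EXPECTED",
      "root": "intent",
      "nodes": {
        "intent": {"field": "record.consult.treatment_intent", "op": "EQ", "value": "CURATIVE", "true": "risk", "false": "na"},
        "risk": {"field": "record.consult.nccn_risk_group", "op": "EQ", "value": "HIGH", "true": "adt", "false": "na"},
        "adt": {"field": "record.consult.hormone_therapy_planned", "op": "EQ", "value": true, "true": "pass", "false": "fail"},
        "pass": {"leaf": "PASS"},
        "fail": {"leaf": "FAIL"},
        "na": {"leaf": "NOT_APPLICABLE"}
      }
    },
    {
      "measure_id": "PROS-DOSE-CURATIVE",
      "title": "Curative-intent prescriptions reach at least 60 Gy equivalent total dose",
      "category": "EXPECTED",
      "root": "intent",
      "nodes": {
        "intent": {"field": "record.consult.treatment_intent", "op": "EQ", "value": "CURATIVE", "true": "dose", "false": "na"},
        "dose": {"field": "plan.prescription_dose", "op": "GE", "value": 60.0, "true": "pass", "false": "fail"},
        "pass": {"leaf": "PASS"},
        "fail": {"leaf": "FAIL"},
        "na": {"leaf": "NOT_APPLICABLE"}
      }
    },
    {
      "measure_id": "PROS-RECTUM-V70",
      "title": "Rectum V70Gy constraint met or within acceptable variation",
      "category": "EXPECTED",
      "root": "status",
      "nodes": {
        "status": {"field": "dvh.Rectum.V70Gy.status", "op": "IN", "value": ["PASS", "VARIATION"], "true": "pass", "false": "fail"},
        "pass": {"leaf": "PASS"},
        "fail": {"leaf": "FAIL"}
      }
    },
    {
      "measure_id": "PROS-COMPLETION",
      "title": "Course completed as prescribed",
      "category": "SURVEILLANCE",
      "root": "done",
      "nodes": {
        "done": {"field": "record.eot.treatment_completed", "op": "EQ", "value": true, "true": "pass", "false": "fail"},
        "pass": {"leaf": "PASS"},
        "fail": {"leaf": "FAIL"}
      }
    }
  ]
}
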