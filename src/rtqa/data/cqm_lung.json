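{
  "ruleset_id": "rtqa-lung-example-v1",
  "comment": "Illustrative structural examples of decision-tree quality measures; not a transcription of any published measure set.",
  "feature_dictionary": [
    "record.disease_site",
    "record.consult.treatment_intent",
    "record.consult.histology",
    "record.consult.concurrent_chemotherapy_planned",
    "record.sim_directive.motion_management",
    "record.eot.treatment_completed",
    "plan.prescription_dose",
    "plan.fractions",
    "dvh.plan_status",
    "dvh.Lungs.V20Gy.status",
    "dvh.SpinalCord.Dmax.status"
  ],
  "measures": [
    {
      "measure_id": "LUNG-MOTION",
      "title": "Curative-intent lung plans use active motion management",
      "category": "EXPECTED",
      "root": "intent",
      "nodes": {
        "intent": {"field": "record.consult.treatment_intent", "op": "EQ", "value": "CURATIVE", "true": "motion", "false": "na"},
        "motion": {"field": "record.sim_directive.motion_management", "op": "IN", "value": ["FOUR_D_CT", "BREATH_HOLD", "ABDOMINAL_COMPRESSION"], "true": "pass", "false": "fail"},
        "pass": {"leaf": "PASS"},
        "fail": {"leaf": "FAIL"},
        "na": {"leaf": "NOT_APPLICABLE"}
      }
    },
    {
      "measure_id": "LUNG-V20",
      "title": "Total lung V20Gy constraint met or within acceptable variation",
      "category": "EXPECTED",
      "root": "status",
      "nodes": {
        "status": {"field": "dvh.Lungs.V20Gy.status", "op": "IN", "value": ["PASS", "VARIATION"], "true": "pass", "false": "fail"},
        "pass": {"leaf": "PASS"},
        "fail": {"leaf": "FAIL"}
      }
    },
    {
      "measure_id": "LUNG-CORD",
      "title": "Spinal cord maximum dose constraint met",
      "category": "EXPECTED",
      "root": "status",
      "nodes": {
        "status": {"field": "dvh.SpinalCord.Dmax.status", "op": "EQ", "value": "PASS", "true": "pass", "false": "fail"},
        "pass": {"leaf": "PASS"},
        "fail": {"leaf": "FAIL"}
      }
    },
    {
      "measure_id": "LUNG-COMPLETION",
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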