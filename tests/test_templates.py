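import itertools

import pytest

from rtqa.errors import ConfigurationError, DomainError, ParseError
from rtqa.synthetic import make_patient_record
from rtqa.templates import (
    PatientRecord,
    Provenance,
    autopopulate,
    compute_nccn_risk,
    extract_discrete,
    load_site_schemas,
    render_narrative,
    validate,
)


@pytest.fixture(scope="module")
def prostate_bundle():
    return load_site_schemas("PROSTATE")


class TestValidate:
    def test_complete_synthetic_consult_is_clean(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=5)
        issues = validate(rec, prostate_bundle["schemas"]["CONSULT"])
        assert [i for i in issues if i.severity == "ERROR"] == []

    def test_out_of_range_psa_is_error(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=5)
        rec.set_field("CONSULT", "psa", -1.0)
        issues = validate(rec, prostate_bundle["schemas"]["CONSULT"])
        assert any(i.severity == "ERROR" and "psa" in i.message and
                   "range" in i.message for i in issues)

    def test_missing_optional_is_warning_only(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=5)
        rec.encounters["CONSULT"].fields.pop("comorbidity", None)
        issues = validate(rec, prostate_bundle["schemas"]["CONSULT"])
        comorbidity = [i for i in issues if i.field == "comorbidity"]
        assert comorbidity and all(i.severity == "WARNING" for i in comorbidity)

    def test_vocabulary_violation_is_error(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=5)
        rec.set_field("CONSULT", "t_stage", "T9")
        issues = validate(rec, prostate_bundle["schemas"]["CONSULT"])
        assert any(i.field == "t_stage" and i.severity == "ERROR" for i in issues)

    def test_validation_is_pure(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=5)
        schema = prostate_bundle["schemas"]["CONSULT"]
        assert validate(rec, schema) == validate(rec, schema)


def _nccn_published_table(t_stage, gleason_sum, psa):
    """Independent encoding of the three-tier clinically-localized risk
    table, written directly from its textual definition."""
    if t_stage in {"T3a", "T3b", "T4"} or gleason_sum >= 8 or psa > 20:
        return "HIGH"
    if t_stage in {"T1a", "T1b", "T1c", "T2a"} and gleason_sum <= 6 and psa < 10:
        return "LOW"
    return "INTERMEDIATE"


_GLEASON_BY_SUM = {6: (3, 3), 7: (3, 4), 8: (4, 4), 9: (4, 5)}


class TestNccnRisk:
    @pytest.mark.parametrize("t,gp,gs,psa,expected", [
        ("T1c", 3, 3, 8.0, "LOW"),
        ("T2b", 3, 4, 12.0, "INTERMEDIATE"),
        ("T2a", 4, 4, 5.0, "HIGH"),  # Gleason 8 dominates
    ])
    def test_worked_examples(self, t, gp, gs, psa, expected):
        assert compute_nccn_risk(t, gp, gs, psa) == expected

    def test_exhaustive_cross_product_matches_published_table(self):
        for t, gsum, psa in itertools.product(
            ["T1c", "T2a", "T2b", "T2c", "T3a"], [6, 7, 8, 9], [5.0, 15.0, 25.0]
        ):
            gp, gs = _GLEASON_BY_SUM[gsum]
            assert compute_nccn_risk(t, gp, gs, psa) == \
                _nccn_published_table(t, gsum, psa), (t, gsum, psa)

    def test_boundaries(self):
        # PSA exactly 10 is not LOW; exactly 20 is not HIGH
        assert compute_nccn_risk("T1c", 3, 3, 10.0) == "INTERMEDIATE"
        assert compute_nccn_risk("T1c", 3, 3, 20.0) == "INTERMEDIATE"

    def test_domain_errors(self):
        with pytest.raises(DomainError):
            compute_nccn_risk("T1c", 2, 3, 5.0)
        with pytest.raises(DomainError):
            compute_nccn_risk("TX", 3, 3, 5.0)


class TestAutopopulate:
    def test_consult_flows_to_eot(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=8)
        eot = rec.encounters["EOT"]
        assert eot.fields["t_stage"] == \
            rec.encounters["CONSULT"].fields["t_stage"]
        assert eot.provenance["t_stage"] == Provenance.AUTO_POPULATED

    def test_manual_edit_wins_and_idempotence(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=8)
        rec.set_field("EOT", "t_stage", "T4")  # marks ENTERED
        before = rec.to_dict()
        autopopulate("EOT", rec, prostate_bundle["flows"],
                     prostate_bundle["schemas"])
        assert rec.to_dict() == before
        assert rec.encounters["EOT"].provenance["t_stage"] == Provenance.ENTERED

    def test_missing_source_warns(self, prostate_bundle):
        rec = PatientRecord("p", "PROSTATE")
        _, warnings = autopopulate("EOT", rec, prostate_bundle["flows"])
        assert len(warnings) == 2

    def test_bad_flow_map_rejected(self, prostate_bundle):
        with pytest.raises(ConfigurationError):
            autopopulate("EOT", PatientRecord("p", "PROSTATE"),
                         {"EOT": [["CONSULT", "nope", "t_stage"]]},
                         prostate_bundle["schemas"])


class TestNarrativeRoundTrip:
    def test_simple_substitution(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=2,
                                  overrides={"psa": 8.0})
        schema = prostate_bundle["schemas"]["CONSULT"]
        text = render_narrative(rec, "PSA was {psa} ng/mL.", "CONSULT", schema)
        assert text == "PSA was 8.0 ng/mL."
        assert extract_discrete(text, "PSA was {psa} ng/mL.", schema) == \
            {"psa": 8.0}

    def test_sentinel_for_absent_optional(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=2)
        rec.encounters["CONSULT"].fields.pop("comorbidity", None)
        schema = prostate_bundle["schemas"]["CONSULT"]
        bp = "Comorbidity: {comorbidity}."
        text = render_narrative(rec, bp, "CONSULT", schema)
        assert "[not recorded]" in text
        assert extract_discrete(text, bp, schema) == {}

    @pytest.mark.parametrize("site", ["PROSTATE", "LUNG"])
    @pytest.mark.parametrize("template_id", ["CONSULT", "EOT"])
    def test_round_trip_on_random_records(self, site, template_id):
        bundle = load_site_schemas(site)
        schema = bundle["schemas"][template_id]
        bp = bundle["boilerplates"][template_id]
        placeholders = {m for m in schema.field_map()
                        if "{%s}" % m in bp}
        for seed in range(25):
            rec = make_patient_record(site, seed=seed)
            text = render_narrative(rec, bp, template_id, schema)
            got = extract_discrete(text, bp, schema)
            fields = rec.encounters[template_id].fields
            expected = {k: v for k, v in fields.items() if k in placeholders}
            assert got == expected, (site, template_id, seed)

    def test_tampered_narrative_raises_with_position(self, prostate_bundle):
        rec = make_patient_record("PROSTATE", seed=2)
        bundle = prostate_bundle
        schema = bundle["schemas"]["EOT"]
        bp = bundle["boilerplates"]["EOT"]
        text = render_narrative(rec, bp, "EOT", schema)
        tampered = text.replace("Treatment completed:", "Tx done:")
        with pytest.raises(ParseError) as exc:
            extract_discrete(tampered, bp, schema)
        assert exc.value.position >= 0

    def test_unknown_placeholder_rejected(self, prostate_bundle):
        schema = prostate_bundle["schemas"]["CONSULT"]
        rec = make_patient_record("PROSTATE", seed=2)
        with pytest.raises(ConfigurationError) as exc:
            render_narrative(rec, "Value: {no_such_field}.", "CONSULT", schema)
        assert "no_such_field" in str(exc.value)

    def test_empty_placeholder_boilerplate(self, prostate_bundle):
        schema = prostate_bundle["schemas"]["CONSULT"]
        assert extract_discrete("Plain text.", "Plain text.", schema) == {}
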