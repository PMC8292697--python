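import itertools
import json

import numpy as np
import pytest

from oracles import eval_tree
from rtqa.cqm import (
    evaluate_measure,
    flatten_features,
    load_example_ruleset,
    load_ruleset,
    replay_trace,
    score_patient,
)
from rtqa.dicom_rt_io import PlanSummary
from rtqa.errors import ConfigurationError, VocabularyError, WiringError
from rtqa.synthetic import make_cohort, make_patient_record


def _ruleset_doc(nodes, root="n0", features=None):
    return {
        "ruleset_id": "t",
        "feature_dictionary": features or [],
        "measures": [{"measure_id": "M", "title": "", "category": "EXPECTED",
                      "root": root, "nodes": nodes}],
    }


HIGH_RISK_ADT = {
    "risk": {"field": "risk", "op": "EQ", "value": "HIGH",
             "true": "adt", "false": "na"},
    "adt": {"field": "hormone_therapy", "op": "EXISTS",
            "true": "pass", "false": "fail"},
    "pass": {"leaf": "PASS"}, "fail": {"leaf": "FAIL"},
    "na": {"leaf": "NOT_APPLICABLE"},
}


class TestLoadRuleset:
    def test_valid_tree_accepted(self):
        rs = load_ruleset(_ruleset_doc(HIGH_RISK_ADT, root="risk",
                                       features=["risk", "hormone_therapy"]))
        assert rs.measures[0].root == "risk"

    def test_self_cycle_rejected_with_path(self):
        nodes = {"n0": {"field": "x", "op": "EQ", "value": 1,
                        "true": "n0", "false": "leaf"},
                 "leaf": {"leaf": "PASS"}}
        with pytest.raises(ConfigurationError) as exc:
            load_ruleset(_ruleset_doc(nodes, features=["x"]))
        assert "cycle" in str(exc.value)
        assert "n0" in str(exc.value)

    def test_dangling_branch_rejected(self):
        nodes = {"n0": {"field": "x", "op": "EQ", "value": 1,
                        "true": "ghost", "false": "leaf"},
                 "leaf": {"leaf": "PASS"}}
        with pytest.raises(ConfigurationError) as exc:
            load_ruleset(_ruleset_doc(nodes, features=["x"]))
        assert "ghost" in str(exc.value)

    def test_typo_feature_names_nearest_known(self):
        nodes = {"n0": {"field": "pssa", "op": "GT", "value": 10,
                        "true": "p", "false": "f"},
                 "p": {"leaf": "PASS"}, "f": {"leaf": "FAIL"}}
        with pytest.raises(VocabularyError) as exc:
            load_ruleset(_ruleset_doc(nodes, features=["psa", "t_stage"]))
        assert "psa" in str(exc.value)

    def test_bundled_example_rulesets_load(self):
        for site in ("prostate", "lung"):
            rs = load_example_ruleset(site)
            assert len(rs.measures) >= 3


class TestEvaluateMeasure:
    def _measure(self):
        return load_ruleset(
            _ruleset_doc(HIGH_RISK_ADT, root="risk",
                         features=["risk", "hormone_therapy"])
        ).measures[0]

    def test_hand_evaluated_pass(self):
        res = evaluate_measure({"risk": "HIGH", "hormone_therapy": True},
                               self._measure())
        assert (res.result, res.score) == ("PASS", 1)
        assert len(res.path_trace) == 3  # risk -> adt -> leaf

    def test_not_applicable_branch(self):
        res = evaluate_measure({"risk": "LOW"}, self._measure())
        assert (res.result, res.score) == ("NOT_APPLICABLE", None)

    def test_missing_field_not_evaluable(self):
        nodes = dict(HIGH_RISK_ADT)
        nodes["adt"] = {"field": "hormone_therapy", "op": "EQ", "value": True,
                        "true": "pass", "false": "fail"}
        m = load_ruleset(_ruleset_doc(nodes, root="risk",
                                      features=["risk", "hormone_therapy"])
                         ).measures[0]
        res = evaluate_measure({"risk": "HIGH"}, m)
        assert res.result == "NOT_EVALUABLE"
        assert res.missing_fields == ["hormone_therapy"]

    def test_exists_never_fails_on_missing(self):
        res = evaluate_measure({"risk": "HIGH"}, self._measure())
        assert res.result == "FAIL"  # EXISTS -> false branch, not NOT_EVALUABLE


def _random_tree(rng, features, domains, max_depth=5):
    """Random acyclic decision tree over categorical features, as a node
    dict compatible with both the engine and the brute-force oracle."""
    nodes = {}
    counter = [0]

    def build(depth):
        nid = f"n{counter[0]}"
        counter[0] += 1
        if depth >= max_depth or rng.random() < 0.3:
            nodes[nid] = {"leaf": str(rng.choice(
                ["PASS", "FAIL", "NOT_APPLICABLE"]))}
            return nid
        f = str(rng.choice(features))
        dom = domains[f]
        op = str(rng.choice(["EQ", "NE", "LE", "IN", "EXISTS"]))
        node = {"field": f, "op": op}
        if op == "IN":
            k = int(rng.integers(1, len(dom) + 1))
            node["value"] = [int(v) for v in rng.choice(dom, size=k,
                                                        replace=False)]
        elif op != "EXISTS":
            node["value"] = int(rng.choice(dom))
        node["true"] = build(depth + 1)
        node["false"] = build(depth + 1)
        nodes[nid] = node
        return nid

    root = build(0)
    return nodes, root


class TestRandomTreeOracle:
    def test_engine_matches_truth_table_enumeration(self):
        rng = np.random.default_rng(2024)
        features = [f"f{i}" for i in range(6)]
        domains = {f: [0, 1] if i % 2 == 0 else [0, 1, 2]
                   for i, f in enumerate(features)}
        for _ in range(15):
            nodes, root = _random_tree(rng, features, domains)
            measure = load_ruleset(
                _ruleset_doc(nodes, root=root, features=features)
            ).measures[0]
            for values in itertools.product(*(domains[f] for f in features)):
                assignment = dict(zip(features, values))
                expected, _ = eval_tree(nodes, root, assignment)
                res = evaluate_measure(assignment, measure)
                assert res.result == expected
                assert replay_trace(measure, res.path_trace) == expected

    def test_missing_feature_assignments_agree_with_oracle(self):
        rng = np.random.default_rng(77)
        features = [f"f{i}" for i in range(4)]
        domains = {f: [0, 1] for f in features}
        for _ in range(10):
            nodes, root = _random_tree(rng, features, domains, max_depth=4)
            measure = load_ruleset(
                _ruleset_doc(nodes, root=root, features=features)
            ).measures[0]
            for values in itertools.product([0, 1, None], repeat=4):
                assignment = {f: v for f, v in zip(features, values)
                              if v is not None}
                expected, missing = eval_tree(nodes, root, assignment)
                res = evaluate_measure(assignment, measure)
                assert res.result == expected
                if missing is not None:
                    assert res.missing_fields == [missing]


class TestScorePatient:
    def _inputs(self, **overrides):
        rec = make_patient_record("PROSTATE", seed=4, overrides=overrides)
        plan = PlanSummary(prescription_dose=78.0, fractions=39)
        member = make_cohort(1, ["A"], seed=4)[0]
        return rec, plan, member.constraint_report

    def test_scorecard_deterministic_serialization(self):
        rules = load_example_ruleset("prostate")
        rec, plan, report = self._inputs()
        a = score_patient(rec, plan, report, rules)
        b = score_patient(rec, plan, report, rules)
        assert json.dumps(a.to_dict(), sort_keys=True) == \
            json.dumps(b.to_dict(), sort_keys=True)
        assert sum(a.summary["by_result"].values()) == \
            a.summary["n_measures"]

    def test_flipping_one_feature_changes_only_dependent_measures(self):
        rules = load_example_ruleset("prostate")
        rec, plan, report = self._inputs(
            treatment_intent="CURATIVE", t_stage="T3a",
            hormone_therapy_planned=True)
        base = score_patient(rec, plan, report, rules)
        rec2, _, _ = self._inputs(
            treatment_intent="CURATIVE", t_stage="T3a",
            hormone_therapy_planned=False)
        flipped = score_patient(rec2, plan, report, rules)
        changed = {m for m in base.results
                   if base.results[m].result != flipped.results[m].result}
        assert changed == {"PROS-ADT-HIGH"}

    def test_empty_ruleset_gives_empty_scorecard(self):
        rules = load_ruleset({"ruleset_id": "e", "feature_dictionary": [],
                              "measures": []})
        rec, plan, report = self._inputs()
        card = score_patient(rec, plan, report, rules)
        assert card.results == {}
        assert card.summary["n_measures"] == 0

    def test_namespace_collision_is_wiring_error(self):
        rec = make_patient_record("PROSTATE", seed=4)
        features = flatten_features(rec)
        assert "record.consult.psa" in features
        rec.encounters["CONSULT"].fields["psa"] = 1.0
        # force a collision by duplicating a namespace key via a crafted record
        class Doubled(dict):
            pass
        with pytest.raises(WiringError):
            # two encounters that flatten to the same key
            rec.encounters["consult"] = rec.encounters["CONSULT"]
            flatten_features(rec)
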