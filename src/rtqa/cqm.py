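"""Clinical quality measures as declarative decision trees.

Each measure is an acyclic binary tree over a flattened feature map drawn
from the clinical record (``record.*``), the plan (``plan.*``) and the
constraint report (``dvh.*``). Decision nodes test one feature with a
comparison operator; leaves declare PASS, FAIL, or NOT_APPLICABLE
(eligibility carve-outs are authored in the tree, never special-cased by the
engine). A predicate over a missing feature makes the measure
NOT_EVALUABLE — missing data is never silently scored as bad care.

All structural errors (cycles, dangling branches, unknown features) are
caught when the ruleset is loaded; evaluation itself cannot fail.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .constraints import ConstraintReport
from .dicom_rt_io import PlanSummary
from .errors import ConfigurationError, VocabularyError, WiringError
from .nomenclature import similarity
from .templates import PatientRecord

OPS = ("EQ", "NE", "LT", "LE", "GT", "GE", "IN", "EXISTS")
LEAVES = ("PASS", "FAIL", "NOT_APPLICABLE")
CATEGORIES = ("EXPECTED", "ASPIRATIONAL", "SURVEILLANCE")


class Result:
    PASS = "PASS"
    FAIL = "FAIL"
    NOT_APPLICABLE = "NOT_APPLICABLE"
    NOT_EVALUABLE = "NOT_EVALUABLE"


@dataclass(frozen=True)
class Predicate:
    field: str
    op: str
    value: object = None


@dataclass
class Node:
    node_id: str
    leaf: Optional[str] = None
    predicate: Optional[Predicate] = None
    true_branch: Optional[str] = None
    false_branch: Optional[str] = None

    @property
    def is_leaf(self) -> bool:
        return self.leaf is not None


@dataclass
class Measure:
    measure_id: str
    title: str
    category: str
    root: str
    nodes: dict


@dataclass
class CQMRuleSet:
    ruleset_id: str
    feature_dictionary: list
    measures: list


@dataclass
class MeasureResult:
    measure_id: str
    result: str
    score: Optional[int]  # 1 iff PASS, 0 iff FAIL, None otherwise
    path_trace: list = field(default_factory=list)  # (node_id, outcome)
    missing_fields: list = field(default_factory=list)


@dataclass
class ScoreCard:
    patient_key: str
    results: dict = field(default_factory=dict)  # measure_id -> MeasureResult
    summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "patient_key": self.patient_key,
            "results": {
                m: {
                    "result": r.result,
                    "score": r.score,
                    "path_trace": list(r.path_trace),
                    "missing_fields": list(r.missing_fields),
                }
                for m, r in sorted(self.results.items())
            },
            "summary": self.summary,
        }


# ---------------------------------------------------------------------------
# Loading and validation
# ---------------------------------------------------------------------------

def _nearest_feature(name: str, dictionary) -> str:
    if not dictionary:
        return ""
    return max(sorted(dictionary), key=lambda f: similarity(name, f))


def load_ruleset(doc_or_path) -> CQMRuleSet:
    """Load and structurally validate a ruleset from a JSON document or path.

    Rejection lists every violation: cycles (with the node path), dangling
    branch ids, malformed nodes, and predicates on features outside the
    declared feature dictionary (naming the nearest known field).
    """
    if isinstance(doc_or_path, dict):
        doc = doc_or_path
    else:
        with open(doc_or_path) as fh:
            doc = json.load(fh)

    dictionary = list(doc.get("feature_dictionary", []))
    problems = []
    measures = []
    for m in doc.get("measures", []):
        mid = m.get("measure_id", "<unnamed>")
        category = m.get("category", "EXPECTED")
        if category not in CATEGORIES:
            problems.append(f"{mid}: unknown category {category}")
        nodes = {}
        for nid, raw in m.get("nodes", {}).items():
            if "leaf" in raw:
                if raw["leaf"] not in LEAVES:
                    problems.append(f"{mid}/{nid}: unknown leaf {raw['leaf']}")
                nodes[nid] = Node(nid, leaf=raw["leaf"])
            else:
                op = raw.get("op")
                if op not in OPS:
                    problems.append(f"{mid}/{nid}: unknown op {op}")
                fieldname = raw.get("field", "")
                if dictionary and fieldname not in dictionary:
                    problems.append(
                        f"{mid}/{nid}: unknown feature '{fieldname}' "
                        f"(nearest known: '{_nearest_feature(fieldname, dictionary)}')"
                    )
                nodes[nid] = Node(
                    nid,
                    predicate=Predicate(fieldname, op, raw.get("value")),
                    true_branch=raw.get("true"),
                    false_branch=raw.get("false"),
                )
        root = m.get("root")
        if root not in nodes:
            problems.append(f"{mid}: root '{root}' is not a node")
        else:
            problems.extend(_check_structure(mid, root, nodes))
        measures.append(
            Measure(mid, m.get("title", ""), category, root, nodes)
        )
    if problems:
        kinds = " | ".join(problems)
        if any("unknown feature" in p for p in problems) and len(problems) == sum(
            1 for p in problems if "unknown feature" in p
        ):
            raise VocabularyError(kinds)
        raise ConfigurationError(kinds)
    return CQMRuleSet(
        ruleset_id=doc.get("ruleset_id", ""),
        feature_dictionary=dictionary,
        measures=measures,
    )


def _check_structure(mid: str, root: str, nodes: dict) -> list:
    problems = []
    # branch resolution
    for nid, node in nodes.items():
        if node.is_leaf:
            continue
        for branch in (node.true_branch, node.false_branch):
            if branch not in nodes:
                problems.append(f"{mid}/{nid}: branch '{branch}' does not resolve")
    if problems:
        return problems
    # cycle detection via DFS with path reporting
    WHITE, GREY, BLACK = 0, 1, 2
    state = {nid: WHITE for nid in nodes}
    path = []

    def dfs(nid):
        state[nid] = GREY
        path.append(nid)
        node = nodes[nid]
        if not node.is_leaf:
            for branch in (node.true_branch, node.false_branch):
                if state[branch] == GREY:
                    cyc = path[path.index(branch):] + [branch]
                    problems.append(f"{mid}: cycle {' -> '.join(cyc)}")
                elif state[branch] == WHITE:
                    dfs(branch)
        path.pop()
        state[nid] = BLACK

    dfs(root)
    return problems


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

_MISSING = object()


def _apply_op(op: str, actual, literal) -> bool:
    if op == "EXISTS":
        return actual is not _MISSING and actual is not None
    if op == "EQ":
        return actual == literal
    if op == "NE":
        return actual != literal
    if op == "IN":
        return actual in literal
    if op == "LT":
        return actual < literal
    if op == "LE":
        return actual <= literal
    if op == "GT":
        return actual > literal
    if op == "GE":
        return actual >= literal
    raise ConfigurationError(f"unknown op {op}")


def evaluate_measure(features: dict, measure: Measure) -> MeasureResult:
    """Walk the tree root-to-leaf over a flattened feature map.

    A predicate (other than EXISTS) on a missing feature halts the walk and
    yields NOT_EVALUABLE with the field recorded; EXISTS treats missing as
    false and never halts.
    """
    trace = []
    nid = measure.root
    while True:
        node = measure.nodes[nid]
        if node.is_leaf:
            trace.append((nid, node.leaf))
            result = node.leaf
            score = {Result.PASS: 1, Result.FAIL: 0}.get(result)
            return MeasureResult(measure.measure_id, result, score, trace, [])
        p = node.predicate
        actual = features.get(p.field, _MISSING)
        if actual is _MISSING and p.op != "EXISTS":
            trace.append((nid, None))
            return MeasureResult(
                measure.measure_id, Result.NOT_EVALUABLE, None, trace, [p.field]
            )
        outcome = _apply_op(p.op, actual, p.value)
        trace.append((nid, outcome))
        nid = node.true_branch if outcome else node.false_branch


def replay_trace(measure: Measure, trace: list) -> str:
    """Re-walk a path trace against the tree; returns the leaf it ends at.

    Used to verify that every reported trace replays to the reported leaf.
    """
    nid = measure.root
    for step_id, outcome in trace:
        if step_id != nid:
            raise WiringError(f"trace diverges at {step_id} (expected {nid})")
        node = measure.nodes[nid]
        if node.is_leaf:
            return node.leaf
        if outcome is None:
            return Result.NOT_EVALUABLE
        nid = node.true_branch if outcome else node.false_branch
    raise WiringError("trace ended before reaching a leaf")


# ---------------------------------------------------------------------------
# Feature flattening and patient scoring
# ---------------------------------------------------------------------------

def flatten_features(record: Optional[PatientRecord] = None,
                     plan: Optional[PlanSummary] = None,
                     constraint_report: Optional[ConstraintReport] = None) -> dict:
    """Flatten the three data sources into one namespaced feature map.

    ``record.<template>.<field>`` (template ids lowercased),
    ``plan.prescription_dose|fractions|dose_per_fraction|technique``, and
    ``dvh.plan_status`` plus ``dvh.<Structure>.<Metric>.status|value`` per
    constraint. A duplicate key is a wiring error.
    """
    features: dict = {}

    def put(key, value):
        if key in features:
            raise WiringError(f"feature namespace collision on '{key}'")
        features[key] = value

    if record is not None:
        put("record.patient_key", record.patient_key)
        put("record.disease_site", record.disease_site)
        for tid, enc in record.encounters.items():
            for name, value in enc.fields.items():
                put(f"record.{tid.lower()}.{name}", value)
    if plan is not None:
        put("plan.prescription_dose", plan.prescription_dose)
        put("plan.fractions", plan.fractions)
        put("plan.dose_per_fraction", plan.dose_per_fraction)
        put("plan.technique", plan.technique)
    if constraint_report is not None:
        put("dvh.plan_status", constraint_report.plan_status)
        for r in constraint_report.results:
            key = f"dvh.{r.constraint.structure}.{r.constraint.metric.label()}"
            put(f"{key}.status", r.status)
            put(f"{key}.value", r.value)
    return {k: v for k, v in features.items() if v is not None}


def score_patient(record: PatientRecord, plan: Optional[PlanSummary],
                  constraint_report: Optional[ConstraintReport],
                  ruleset: CQMRuleSet) -> ScoreCard:
    """Evaluate every measure of ``ruleset`` for one patient."""
    features = flatten_features(record, plan, constraint_report)
    card = ScoreCard(patient_key=record.patient_key)
    by_result: dict = {}
    by_category: dict = {}
    for measure in ruleset.measures:
        res = evaluate_measure(features, measure)
        card.results[measure.measure_id] = res
        by_result[res.result] = by_result.get(res.result, 0) + 1
        by_category.setdefault(measure.category, {})
        by_category[measure.category][res.result] = (
            by_category[measure.category].get(res.result, 0) + 1
        )
    card.summary = {"by_result": by_result, "by_category": by_category,
                    "n_measures": len(ruleset.measures)}
    return card


def load_example_ruleset(site: str) -> CQMRuleSet:
    """Bundled illustrative ruleset for "prostate" or "lung" (structural
    examples, not transcriptions of any published measure set)."""
    name = f"cqm_{site.lower()}.json"
    text = resources.files("rtqa.data").joinpath(name).read_text()
    return load_ruleset(json.loads(text))
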