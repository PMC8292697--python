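"""Dose-constraint grading: pass / acceptable variation / fail.

Constraint sets are editable JSON per disease site; no limits are hard-coded.
Boundary equality satisfies a limit (<= / >= semantics), matching how
published constraint tables are written.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .dvh import DVHCurve, MetricSpec, evaluate_metric, parse_metric
from .errors import ConfigurationError, DomainError, WiringError


class Status:
    PASS = "PASS"
    VARIATION = "VARIATION"
    FAIL = "FAIL"
    NOT_EVALUABLE = "NOT_EVALUABLE"


_SEVERITY = {Status.PASS: 0, Status.VARIATION: 1, Status.FAIL: 2}


class Comparator:
    LE = "LE"
    GE = "GE"


@dataclass(frozen=True)
class DoseConstraint:
    structure: str  # TG-263 name
    metric: MetricSpec
    comparator: str  # LE | GE
    pass_limit: float
    variation_limit: Optional[float] = None
    source_label: str = ""

    def __post_init__(self):
        if self.comparator not in (Comparator.LE, Comparator.GE):
            raise ConfigurationError(f"unknown comparator {self.comparator}")
        if self.variation_limit is not None:
            looser = (
                self.variation_limit >= self.pass_limit
                if self.comparator == Comparator.LE
                else self.variation_limit <= self.pass_limit
            )
            if not looser:
                raise ConfigurationError(
                    f"variation limit {self.variation_limit} tighter than "
                    f"pass limit {self.pass_limit} under {self.comparator}"
                )

    def label(self) -> str:
        return f"{self.metric.label()}({self.structure})"


@dataclass
class ConstraintResult:
    constraint: DoseConstraint
    value: Optional[float]
    status: str
    reason: str = ""


@dataclass
class ConstraintReport:
    results: list = field(default_factory=list)

    @property
    def plan_status(self) -> str:
        """Worst status over evaluable constraints; NOT_EVALUABLE rows are
        listed but never counted."""
        worst = Status.PASS
        for r in self.results:
            if r.status == Status.NOT_EVALUABLE:
                continue
            if _SEVERITY[r.status] > _SEVERITY[worst]:
                worst = r.status
        return worst

    def to_dict(self) -> dict:
        return {
            "plan_status": self.plan_status,
            "constraints": [
                {
                    "structure": r.constraint.structure,
                    "metric": r.constraint.metric.label(),
                    "comparator": r.constraint.comparator,
                    "pass_limit": r.constraint.pass_limit,
                    "variation_limit": r.constraint.variation_limit,
                    "value": r.value,
                    "status": r.status,
                    "reason": r.reason,
                }
                for r in self.results
            ],
        }


def _satisfies(value: float, limit: float, comparator: str) -> bool:
    return value <= limit if comparator == Comparator.LE else value >= limit


def evaluate_constraint(curve: DVHCurve, c: DoseConstraint) -> ConstraintResult:
    """Grade one constraint against one structure's DVH curve."""
    if curve.structure_name != c.structure:
        raise WiringError(
            f"curve is for '{curve.structure_name}', constraint for '{c.structure}'"
        )
    try:
        value = evaluate_metric(curve, c.metric)
    except DomainError as exc:
        return ConstraintResult(c, None, Status.NOT_EVALUABLE, str(exc))
    if _satisfies(value, c.pass_limit, c.comparator):
        status, reason = Status.PASS, "within pass limit"
    elif c.variation_limit is not None and _satisfies(
        value, c.variation_limit, c.comparator
    ):
        status, reason = Status.VARIATION, "within acceptable variation"
    else:
        status, reason = Status.FAIL, "outside all limits"
    return ConstraintResult(c, value, status, reason)


def evaluate_plan(curves: dict, constraints: list) -> ConstraintReport:
    """Grade a full constraint set against per-structure DVH curves.

    ``curves`` maps TG-263 name -> DVHCurve. Constraints referencing absent
    structures become NOT_EVALUABLE rows and never affect the plan status.
    """
    report = ConstraintReport()
    for c in constraints:
        curve = curves.get(c.structure)
        if curve is None:
            report.results.append(
                ConstraintResult(
                    c, None, Status.NOT_EVALUABLE,
                    f"structure '{c.structure}' absent from case",
                )
            )
            continue
        report.results.append(evaluate_constraint(curve, c))
    return report


def load_constraints(path=None, site: Optional[str] = None) -> list:
    """Load a constraint set from JSON; with no path, the bundled example set
    for ``site`` ("prostate" or "lung"). The shipped sets are illustrative
    examples, not a clinical protocol."""
    if path is None:
        if site is None:
            raise ConfigurationError("either a path or a site is required")
        name = f"constraints_{site.lower()}.json"
        text = resources.files("rtqa.data").joinpath(name).read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    out = []
    for i, row in enumerate(doc["constraints"]):
        for key in ("structure", "metric", "comparator", "pass_limit"):
            if key not in row:
                raise ConfigurationError(f"constraint {i} missing '{key}'")
        out.append(
            DoseConstraint(
                structure=row["structure"],
                metric=parse_metric(row["metric"]),
                comparator=row["comparator"],
                pass_limit=float(row["pass_limit"]),
                variation_limit=(
                    float(row["variation_limit"])
                    if row.get("variation_limit") is not None
                    else None
                ),
                source_label=row.get("source_label", doc.get("source_label", "")),
            )
        )
    return out
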