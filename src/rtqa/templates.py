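"""Discrete clinical data capture across the radiotherapy workflow.

Encounter templates (consult, simulation directive, on-treatment visit,
end of treatment, follow-up) are defined as JSON schemas per disease site,
with field vocabularies drawn from the standard clinical nomenclatures
(AJCC staging labels, CTCAE toxicity grades 0-5). The module validates
records against the schemas, auto-calculates derived elements (NCCN prostate
risk group), auto-populates later templates from earlier ones via a declared
field-flow map, and renders/parses deterministic narrative notes so that
every discrete element survives a round trip through free text.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

from .errors import ConfigurationError, DomainError, ParseError, RtqaError

TEMPLATE_IDS = ("CONSULT", "SIM_DIRECTIVE", "OTV", "EOT", "FOLLOWUP")
SENTINEL = "[not recorded]"


class Provenance:
    ENTERED = "ENTERED"
    IMPORTED = "IMPORTED"
    AUTO_CALCULATED = "AUTO_CALCULATED"
    AUTO_POPULATED = "AUTO_POPULATED"


class Severity:
    ERROR = "ERROR"
    WARNING = "WARNING"


@dataclass(frozen=True)
class ValidationIssue:
    field: str
    severity: str
    message: str


@dataclass
class FieldDef:
    name: str
    type: str  # number | integer | string | date | boolean | vocab
    required: bool = False
    range: Optional[tuple] = None
    vocabulary: Optional[list] = None
    vocab_source: str = ""
    unit: str = ""


@dataclass
class TemplateSchema:
    template_id: str
    disease_site: str
    fields: list

    def __post_init__(self):
        if self.template_id not in TEMPLATE_IDS:
            raise ConfigurationError(f"unknown template_id {self.template_id}")
        names = [f.name for f in self.fields]
        if len(names) != len(set(names)):
            raise ConfigurationError("duplicate field names in template schema")
        for f in self.fields:
            if f.required and f.type == "vocab" and not f.vocabulary:
                raise ConfigurationError(
                    f"required vocab field '{f.name}' lacks a vocabulary"
                )

    def field_map(self) -> dict:
        return {f.name: f for f in self.fields}


@dataclass
class Encounter:
    template_id: str
    timestamp: Optional[str] = None  # ISO date
    fields: dict = field(default_factory=dict)
    provenance: dict = field(default_factory=dict)


@dataclass
class PatientRecord:
    """Discrete clinical record: identity attributes plus one encounter per
    workflow template, with per-field provenance."""

    patient_key: str
    disease_site: str
    identity: dict = field(default_factory=dict)
    encounters: dict = field(default_factory=dict)

    def set_field(self, template_id: str, name: str, value,
                  provenance: str = Provenance.ENTERED) -> None:
        enc = self.encounters.setdefault(template_id, Encounter(template_id))
        enc.fields[name] = value
        enc.provenance[name] = provenance

    def get_field(self, template_id: str, name: str, default=None):
        enc = self.encounters.get(template_id)
        if enc is None:
            return default
        return enc.fields.get(name, default)

    def to_dict(self) -> dict:
        return {
            "patient_key": self.patient_key,
            "disease_site": self.disease_site,
            "identity": dict(self.identity),
            "encounters": {
                t: {
                    "timestamp": e.timestamp,
                    "fields": dict(e.fields),
                    "provenance": dict(e.provenance),
                }
                for t, e in self.encounters.items()
            },
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "PatientRecord":
        rec = cls(
            patient_key=doc["patient_key"],
            disease_site=doc["disease_site"],
            identity=dict(doc.get("identity", {})),
        )
        for t, e in doc.get("encounters", {}).items():
            rec.encounters[t] = Encounter(
                template_id=t,
                timestamp=e.get("timestamp"),
                fields=dict(e.get("fields", {})),
                provenance=dict(e.get("provenance", {})),
            )
        return rec


# ---------------------------------------------------------------------------
# Schema loading
# ---------------------------------------------------------------------------

def load_site_schemas(disease_site: str, path=None) -> dict:
    """Load all template schemas for a disease site.

    Returns ``{"schemas": {template_id: TemplateSchema}, "flows": flow map,
    "boilerplates": {template_id: text}}``. With no path, the bundled
    representative schemas for PROSTATE or LUNG are used.
    """
    site = disease_site.upper()
    if path is None:
        name = f"templates_{site.lower()}.json"
        try:
            text = resources.files("rtqa.data").joinpath(name).read_text()
        except FileNotFoundError:
            raise ConfigurationError(f"no bundled schemas for site {site}")
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    schemas = {}
    for tid, spec in doc["templates"].items():
        fields = [
            FieldDef(
                name=f["name"],
                type=f["type"],
                required=bool(f.get("required", False)),
                range=tuple(f["range"]) if f.get("range") else None,
                vocabulary=list(f["vocabulary"]) if f.get("vocabulary") else None,
                vocab_source=f.get("vocab_source", ""),
                unit=f.get("unit", ""),
            )
            for f in spec["fields"]
        ]
        schemas[tid] = TemplateSchema(tid, site, fields)
    flows = doc.get("flows", {})
    _check_flows(flows, schemas)
    return {
        "schemas": schemas,
        "flows": flows,
        "boilerplates": doc.get("boilerplates", {}),
    }


def _check_flows(flows: dict, schemas: dict) -> None:
    for target, rules in flows.items():
        if target not in schemas:
            raise ConfigurationError(f"flow targets unknown template {target}")
        for src_tid, src_field, dst_field in rules:
            if src_tid not in schemas:
                raise ConfigurationError(f"flow source template {src_tid} unknown")
            if src_field not in schemas[src_tid].field_map():
                raise ConfigurationError(
                    f"flow source field {src_tid}.{src_field} unknown"
                )
            if dst_field not in schemas[target].field_map():
                raise ConfigurationError(
                    f"flow target field {target}.{dst_field} unknown"
                )


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")


def _check_type(value, fd: FieldDef) -> Optional[str]:
    if fd.type == "number":
        if not isinstance(value, (int, float)) or isinstance(value, bool):
            return f"{fd.name} must be a number"
    elif fd.type == "integer":
        if not isinstance(value, int) or isinstance(value, bool):
            return f"{fd.name} must be an integer"
    elif fd.type == "boolean":
        if not isinstance(value, bool):
            return f"{fd.name} must be a boolean"
    elif fd.type == "date":
        if not isinstance(value, str) or not _DATE_RE.match(value):
            return f"{fd.name} must be an ISO date (YYYY-MM-DD)"
    elif fd.type in ("string", "vocab"):
        if not isinstance(value, str):
            return f"{fd.name} must be a string"
    return None


def validate(record: PatientRecord, schema: TemplateSchema) -> list:
    """Validate one encounter of ``record`` against ``schema``.

    Missing required field or range/vocabulary violation -> ERROR; missing
    optional field -> WARNING; a clean encounter yields an empty list.
    Validation is pure: same inputs, same issues.
    """
    enc = record.encounters.get(schema.template_id)
    fields = enc.fields if enc else {}
    issues = []
    for fd in schema.fields:
        if fd.name not in fields or fields[fd.name] is None:
            if fd.required:
                issues.append(ValidationIssue(
                    fd.name, Severity.ERROR, f"required field {fd.name} missing"
                ))
            else:
                issues.append(ValidationIssue(
                    fd.name, Severity.WARNING, f"optional field {fd.name} missing"
                ))
            continue
        value = fields[fd.name]
        type_err = _check_type(value, fd)
        if type_err:
            issues.append(ValidationIssue(fd.name, Severity.ERROR, type_err))
            continue
        if fd.range is not None and not (fd.range[0] <= value <= fd.range[1]):
            issues.append(ValidationIssue(
                fd.name, Severity.ERROR,
                f"{fd.name} out of range [{fd.range[0]}, {fd.range[1]}]: {value}",
            ))
        if fd.vocabulary is not None and value not in fd.vocabulary:
            issues.append(ValidationIssue(
                fd.name, Severity.ERROR,
                f"{fd.name} value '{value}' not in vocabulary"
                + (f" ({fd.vocab_source})" if fd.vocab_source else ""),
            ))
    known = set(schema.field_map())
    for name in fields:
        if name not in known:
            issues.append(ValidationIssue(
                name, Severity.WARNING, f"field {name} not declared in schema"
            ))
    return issues


def validate_record(record: PatientRecord, schemas: dict) -> dict:
    """Validate every encounter present in the record; returns issues per
    template id."""
    return {
        tid: validate(record, schemas[tid])
        for tid in record.encounters
        if tid in schemas
    }


# ---------------------------------------------------------------------------
# Derived fields: NCCN prostate risk group
# ---------------------------------------------------------------------------

def _load_nccn_config() -> dict:
    text = resources.files("rtqa.data").joinpath("nccn_risk.json").read_text()
    return json.loads(text)


_NCCN = None


def compute_nccn_risk(t_stage: str, gleason_primary: int,
                      gleason_secondary: int, psa: float,
                      config: Optional[dict] = None) -> str:
    """NCCN three-tier risk group for clinically localized prostate cancer.

    LOW requires T <= T2a and Gleason sum <= 6 and PSA < 10 ng/mL; HIGH if
    T >= T3a or Gleason sum >= 8 or PSA > 20; everything else is
    INTERMEDIATE. The rule table is configuration (versioned JSON), not code.
    """
    global _NCCN
    if config is None:
        if _NCCN is None:
            _NCCN = _load_nccn_config()
        config = _NCCN
    order = config["t_order"]
    if t_stage not in order:
        raise DomainError(f"unknown T stage label '{t_stage}'")
    for g in (gleason_primary, gleason_secondary):
        if not isinstance(g, int) or not (3 <= g <= 5):
            raise DomainError(f"Gleason component {g} outside 3-5")
    if psa < 0:
        raise DomainError("PSA must be non-negative")

    t_rank = order.index(t_stage)
    gsum = gleason_primary + gleason_secondary
    high = config["high"]
    low = config["low"]
    if (
        t_rank >= order.index(high["t_min"])
        or gsum >= high["gleason_sum_min"]
        or psa > high["psa_gt"]
    ):
        return "HIGH"
    if (
        t_rank <= order.index(low["t_max"])
        and gsum <= low["gleason_sum_max"]
        and psa < low["psa_lt"]
    ):
        return "LOW"
    return "INTERMEDIATE"


# ---------------------------------------------------------------------------
# Auto-population
# ---------------------------------------------------------------------------

def autopopulate(target_template: str, record: PatientRecord,
                 flows: dict, schemas: Optional[dict] = None):
    """Copy declared fields from earlier encounters into ``target_template``.

    Copied fields are marked AUTO_POPULATED. Fields the user has already
    entered are never overwritten, which makes re-running idempotent. A
    missing source field leaves the target absent and records a warning.
    Returns ``(record, warnings)``; the record is modified in place.
    """
    if schemas is not None:
        _check_flows(flows, schemas)
    rules = flows.get(target_template)
    if rules is None:
        raise ConfigurationError(f"no flow rules for template {target_template}")
    warnings = []
    for src_tid, src_field, dst_field in rules:
        src = record.encounters.get(src_tid)
        if src is None or src_field not in src.fields:
            warnings.append(
                f"source {src_tid}.{src_field} absent; {dst_field} left empty"
            )
            continue
        enc = record.encounters.setdefault(
            target_template, Encounter(target_template)
        )
        prov = enc.provenance.get(dst_field)
        if dst_field in enc.fields and prov not in (None, Provenance.AUTO_POPULATED):
            continue  # manual entry wins
        enc.fields[dst_field] = src.fields[src_field]
        enc.provenance[dst_field] = Provenance.AUTO_POPULATED
    return record, warnings


# ---------------------------------------------------------------------------
# Narrative render / extract
# ---------------------------------------------------------------------------

_PLACEHOLDER_RE = re.compile(r"\{([A-Za-z_][A-Za-z0-9_]*)\}")


def _split_boilerplate(boilerplate: str, known_fields) -> tuple:
    """Split into (literals, placeholders); literals has len(placeholders)+1."""
    literals = []
    fields_ = []
    pos = 0
    for m in _PLACEHOLDER_RE.finditer(boilerplate):
        if m.group(1) not in known_fields:
            raise ConfigurationError(
                f"placeholder '{{{m.group(1)}}}' names no schema field"
            )
        literals.append(boilerplate[pos:m.start()])
        fields_.append(m.group(1))
        pos = m.end()
    literals.append(boilerplate[pos:])
    for i in range(1, len(literals) - 1):
        if literals[i] == "":
            raise ConfigurationError(
                "adjacent placeholders without separating text are ambiguous"
            )
    return literals, fields_


def _format_value(value) -> str:
    if value is None:
        return SENTINEL
    if isinstance(value, bool):
        return "true" if value else "false"
    return str(value)


def render_narrative(record: PatientRecord, boilerplate: str,
                     template_id: str, schema: TemplateSchema) -> str:
    """Substitute ``{field}`` placeholders with the encounter's values.

    Absent optional fields render the sentinel ``[not recorded]``; output is
    deterministic.
    """
    known = set(schema.field_map())
    literals, fields_ = _split_boilerplate(boilerplate, known)
    enc = record.encounters.get(template_id)
    values = enc.fields if enc else {}
    parts = [literals[0]]
    for name, lit in zip(fields_, literals[1:]):
        parts.append(_format_value(values.get(name)))
        parts.append(lit)
    return "".join(parts)


def extract_discrete(narrative: str, boilerplate: str,
                     schema: TemplateSchema) -> dict:
    """Inverse of :func:`render_narrative`: recover the substituted field
    values from a narrative. Sentinel values map back to absent fields.
    Raises :class:`ParseError` (with position) when the narrative does not
    match the boilerplate skeleton."""
    known = schema.field_map()
    literals, fields_ = _split_boilerplate(boilerplate, set(known))
    pos = 0
    if not narrative.startswith(literals[0]):
        raise ParseError("narrative does not start with the template text", 0)
    pos = len(literals[0])
    out = {}
    for i, name in enumerate(fields_):
        lit = literals[i + 1]
        if lit == "":
            raw = narrative[pos:]
            pos = len(narrative)
        else:
            nxt = narrative.find(lit, pos)
            if nxt < 0:
                raise ParseError(
                    f"expected text {lit[:30]!r} not found after field '{name}'",
                    pos,
                )
            raw = narrative[pos:nxt]
            pos = nxt + len(lit)
        if raw == SENTINEL:
            continue
        out[name] = _coerce(raw, known[name], pos)
    if pos != len(narrative):
        raise ParseError("unexpected trailing text after template", pos)
    return out


def _coerce(raw: str, fd: FieldDef, pos: int):
    try:
        if fd.type == "number":
            return float(raw)
        if fd.type == "integer":
            return int(raw)
        if fd.type == "boolean":
            if raw in ("true", "false"):
                return raw == "true"
            raise ValueError(raw)
        return raw
    except ValueError:
        raise ParseError(
            f"value {raw!r} for field '{fd.name}' is not a valid {fd.type}", pos
        )
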