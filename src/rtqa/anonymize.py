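"""De-identification with consistent pseudonymization and payload integrity.

Pseudonyms and remapped UIDs come from a keyed one-way derivation (HMAC-SHA256
under a secret key held in the anonymization map store): re-identification is
impossible without the key, but the same original always maps to the same
pseudonym, preserving longitudinal linkage. Dates are shifted by one uniform
per-patient offset so every interval (e.g. treatment duration) survives
de-identification. Export bundles are sealed with a SHA-256 digest over a
canonical key-sorted serialization; a failed verification is recorded in an
audit trail and the contract is reject-do-not-process.
"""

from __future__ import annotations

import datetime
import hashlib
import hmac
import json
import re
import secrets
from dataclasses import dataclass, field
from importlib import resources
from typing import Optional

import pydicom

from .errors import ConfigurationError, RtqaError, UnhandledIdentifierError
from .templates import PatientRecord


class Action:
    REMOVE = "REMOVE"
    REPLACE_DUMMY = "REPLACE_DUMMY"
    HASH_PSEUDONYM = "HASH_PSEUDONYM"
    KEEP = "KEEP"
    SHIFT_DATE = "SHIFT_DATE"


_ACTIONS = {Action.REMOVE, Action.REPLACE_DUMMY, Action.HASH_PSEUDONYM,
            Action.KEEP, Action.SHIFT_DATE}

# identity attributes every policy must explicitly action (fail closed)
MANDATORY_IDENTITY_FIELDS = (
    "patient_name", "patient_mrn", "birth_date", "address", "phone",
)

_DATE_FIELD_RE = re.compile(r".*_date$")
_ISO_DATE_RE = re.compile(r"^\d{4}-\d{2}-\d{2}$")

# DICOM standard class/transfer-syntax UIDs are never remapped
_STANDARD_UID_PREFIX = "1.2.840.10008"


@dataclass
class AnonymizationPolicy:
    identity_actions: dict  # record identity attribute -> action
    dicom_actions: dict  # DICOM keyword -> action
    uid_root: str = "2.25"
    date_shift_range_days: int = 60
    default_clinical_action: Optional[str] = None  # explicit opt-in only

    def __post_init__(self):
        for fmap in (self.identity_actions, self.dicom_actions):
            for name, action in fmap.items():
                if action not in _ACTIONS:
                    raise ConfigurationError(f"unknown action {action} for {name}")
        for name in MANDATORY_IDENTITY_FIELDS:
            if name not in self.identity_actions:
                raise ConfigurationError(
                    f"policy does not cover mandatory identifier '{name}'"
                )
            if self.identity_actions[name] == Action.KEEP:
                raise ConfigurationError(
                    f"mandatory identifier '{name}' must not be kept"
                )
        if self.date_shift_range_days < 1:
            raise ConfigurationError("date_shift_range_days must be >= 1")


def load_policy(path=None) -> AnonymizationPolicy:
    if path is None:
        text = resources.files("rtqa.data").joinpath("anonymization_policy.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    return AnonymizationPolicy(
        identity_actions=doc["identity_actions"],
        dicom_actions=doc["dicom_actions"],
        uid_root=doc.get("uid_root", "2.25"),
        date_shift_range_days=int(doc.get("date_shift_range_days", 60)),
        default_clinical_action=doc.get("default_clinical_action"),
    )


@dataclass
class AnonymizationMap:
    """Persistent keyed pseudonym store for one export stream.

    ``secret_key`` drives every derivation; ``entries`` records
    original -> pseudonym pairs; ``date_offsets`` records the per-patient
    day offset. The map file must be access-restricted: it is the only path
    back to the originals.
    """

    secret_key: str = ""
    entries: dict = field(default_factory=dict)
    date_offsets: dict = field(default_factory=dict)

    def __post_init__(self):
        if not self.secret_key:
            self.secret_key = secrets.token_hex(16)

    def _hmac(self, text: str) -> bytes:
        return hmac.new(self.secret_key.encode(), text.encode(),
                        hashlib.sha256).digest()

    def pseudonym(self, original: str, prefix: str = "PSN") -> str:
        if original in self.entries:
            return self.entries[original]
        token = self._hmac("id:" + original).hex()[:12].upper()
        psn = f"{prefix}-{token}"
        self.entries[original] = psn
        return psn

    def date_offset(self, patient_key: str, range_days: int) -> int:
        if patient_key not in self.date_offsets:
            h = int.from_bytes(self._hmac("date:" + patient_key)[:8], "big")
            self.date_offsets[patient_key] = h % (2 * range_days + 1) - range_days
        return self.date_offsets[patient_key]

    def remap_uid(self, original: str, uid_root: str) -> str:
        if original in self.entries:
            return self.entries[original]
        h = int.from_bytes(self._hmac("uid:" + original), "big") % 10**30
        uid = f"{uid_root}.{h}"
        self.entries[original] = uid
        return uid

    def to_dict(self) -> dict:
        return {
            "secret_key": self.secret_key,
            "entries": dict(self.entries),
            "date_offsets": dict(self.date_offsets),
        }

    @classmethod
    def from_dict(cls, doc: dict) -> "AnonymizationMap":
        return cls(
            secret_key=doc["secret_key"],
            entries=dict(doc.get("entries", {})),
            date_offsets=dict(doc.get("date_offsets", {})),
        )


def _shift_iso_date(value: str, offset_days: int) -> str:
    d = datetime.date.fromisoformat(value)
    return (d + datetime.timedelta(days=offset_days)).isoformat()


# ---------------------------------------------------------------------------
# Record anonymization
# ---------------------------------------------------------------------------

def anonymize_record(record: PatientRecord, policy: AnonymizationPolicy,
                     amap: AnonymizationMap):
    """De-identify a clinical record; returns ``(new_record, amap)``.

    Identity attributes are actioned per policy (fail closed: an identity
    attribute absent from the policy raises). ``patient_key`` is replaced by
    a keyed pseudonym. Every ``*_date`` field is shifted by one consistent
    per-patient offset.
    """
    offset = amap.date_offset(record.patient_key, policy.date_shift_range_days)
    new_key = amap.pseudonym(record.patient_key, prefix="PT")

    identity = {}
    for name, value in record.identity.items():
        action = policy.identity_actions.get(name)
        if action is None:
            raise UnhandledIdentifierError(
                f"identity attribute '{name}' not covered by policy"
            )
        if action == Action.REMOVE:
            continue
        if action == Action.REPLACE_DUMMY:
            identity[name] = "REDACTED"
        elif action == Action.HASH_PSEUDONYM:
            identity[name] = amap.pseudonym(str(value))
        elif action == Action.SHIFT_DATE:
            identity[name] = _shift_iso_date(str(value), offset)
        elif action == Action.KEEP:
            identity[name] = value

    out = PatientRecord(patient_key=new_key,
                        disease_site=record.disease_site,
                        identity=identity)
    for tid, enc in record.encounters.items():
        for name, value in enc.fields.items():
            if _DATE_FIELD_RE.match(name) or (
                isinstance(value, str) and _ISO_DATE_RE.match(value)
            ):
                new_value = (
                    _shift_iso_date(value, offset)
                    if isinstance(value, str) and _ISO_DATE_RE.match(value)
                    else value
                )
            elif policy.default_clinical_action == Action.KEEP:
                new_value = value
            else:
                raise UnhandledIdentifierError(
                    f"clinical field '{tid}.{name}' has no policy action and "
                    "the policy declares no default_clinical_action"
                )
            out.set_field(tid, name, new_value,
                          provenance=enc.provenance.get(name, "ENTERED"))
        out.encounters[tid].timestamp = (
            _shift_iso_date(enc.timestamp, offset)
            if enc.timestamp and _ISO_DATE_RE.match(enc.timestamp)
            else enc.timestamp
        )
    return out, amap


# ---------------------------------------------------------------------------
# DICOM anonymization
# ---------------------------------------------------------------------------

def _walk_remap_uids(ds, amap: AnonymizationMap, uid_root: str) -> None:
    for elem in ds.iterall():
        if elem.VR == "UI":
            if elem.VM > 1:
                elem.value = [
                    v if str(v).startswith(_STANDARD_UID_PREFIX)
                    else amap.remap_uid(str(v), uid_root)
                    for v in elem.value
                ]
            else:
                v = str(elem.value)
                if v and not v.startswith(_STANDARD_UID_PREFIX):
                    elem.value = amap.remap_uid(v, uid_root)


def anonymize_dicom(ds: pydicom.Dataset, policy: AnonymizationPolicy,
                    amap: AnonymizationMap) -> pydicom.Dataset:
    """De-identify one DICOM dataset in place (and return it).

    Identifying attributes are actioned per ``policy.dicom_actions``; every
    non-standard UID anywhere in the dataset (including nested sequences and
    file meta) is remapped deterministically under ``policy.uid_root``, so a
    structure-set/dose/plan triplet processed with one map keeps consistent
    cross-references.
    """
    offset_key = str(ds.get("PatientID", ""))
    offset = amap.date_offset("dicom:" + offset_key,
                              policy.date_shift_range_days)
    for keyword, action in policy.dicom_actions.items():
        if keyword not in ds:
            continue
        if action == Action.REMOVE:
            delattr(ds, keyword)
        elif action == Action.REPLACE_DUMMY:
            setattr(ds, keyword, "ANON")
        elif action == Action.HASH_PSEUDONYM:
            setattr(ds, keyword, amap.pseudonym(str(getattr(ds, keyword))))
        elif action == Action.SHIFT_DATE:
            value = str(getattr(ds, keyword))
            if len(value) == 8 and value.isdigit():
                d = datetime.date(int(value[:4]), int(value[4:6]), int(value[6:8]))
                d += datetime.timedelta(days=offset)
                setattr(ds, keyword, d.strftime("%Y%m%d"))
    _walk_remap_uids(ds, amap, policy.uid_root)
    if hasattr(ds, "file_meta") and ds.file_meta is not None:
        _walk_remap_uids(ds.file_meta, amap, policy.uid_root)
        # keep media storage instance UID aligned with the dataset
        if "SOPInstanceUID" in ds:
            ds.file_meta.MediaStorageSOPInstanceUID = ds.SOPInstanceUID
    return ds


def check_triplet_consistency(datasets) -> None:
    """Verify every UID cross-reference inside the triplet resolves within it.

    Frame-of-reference and referenced SOP instance UIDs present in one
    dataset must appear as a declared UID somewhere in the triplet.
    """
    declared = set()
    for ds in datasets:
        for elem in ds.iterall():
            if elem.VR == "UI":
                for v in ([elem.value] if elem.VM <= 1 else list(elem.value)):
                    declared.add(str(v))
    for ds in datasets:
        for keyword in ("FrameOfReferenceUID", "ReferencedFrameOfReferenceUID"):
            if keyword in ds and str(getattr(ds, keyword)) not in declared:
                raise RtqaError(
                    f"cross-reference {keyword} does not resolve in triplet"
                )


# ---------------------------------------------------------------------------
# Integrity envelope
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class IntegrityEnvelope:
    digest: str
    algorithm: str = "sha256"


def _canonical_bytes(payload) -> bytes:
    if isinstance(payload, bytes):
        return payload
    if isinstance(payload, str):
        return payload.encode()
    return json.dumps(payload, sort_keys=True,
                      separators=(",", ":"), default=str).encode()


def seal(payload) -> IntegrityEnvelope:
    """Digest a payload (bytes, text, or a JSON-able object) over its
    canonical serialization."""
    return IntegrityEnvelope(
        digest=hashlib.sha256(_canonical_bytes(payload)).hexdigest()
    )


def verify(payload, envelope: IntegrityEnvelope,
           audit_trail: Optional[list] = None) -> bool:
    """True iff the payload's recomputed digest matches the envelope.

    Never raises: a mismatch (or an unsupported algorithm label) returns
    False and appends an entry to ``audit_trail``; the caller's contract is
    to reject the transaction without processing the data.
    """
    if envelope.algorithm != "sha256":
        if audit_trail is not None:
            audit_trail.append({
                "event": "integrity_check_failed",
                "reason": f"unsupported algorithm '{envelope.algorithm}'",
            })
        return False
    ok = hmac.compare_digest(
        hashlib.sha256(_canonical_bytes(payload)).hexdigest(), envelope.digest
    )
    if not ok and audit_trail is not None:
        audit_trail.append({
            "event": "integrity_check_failed",
            "reason": "digest mismatch; transaction rejected",
        })
    return ok
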