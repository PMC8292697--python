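"""TG-263 structure-name standardization.

Raw planning-system names are matched against a lexicon of canonical TG-263
names and synonyms: exact and synonym hits score 1.0; otherwise ranked fuzzy
candidates are offered by normalized edit similarity. Suggestions are for a
human to confirm — nothing below score 1.0 is ever applied automatically, and
applying a mapping is a separate, explicit act.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field, replace
from importlib import resources
from typing import Optional

import edlib

from .dicom_rt_io import StructureSet
from .errors import ConfigurationError, MappingConflictError, RtqaError

_LATERALITY = {"lt": "l", "left": "l", "l": "l", "rt": "r", "right": "r", "r": "r"}


class MatchKind:
    EXACT = "EXACT"
    SYNONYM = "SYNONYM"
    FUZZY = "FUZZY"


@dataclass(frozen=True)
class Suggestion:
    tg263_name: str
    score: float
    match_kind: str


@dataclass
class LexiconEntry:
    tg263_name: str
    category: str  # TARGET | OAR
    synonyms: list = field(default_factory=list)


@dataclass
class Lexicon:
    entries: list
    version: str = ""

    def __post_init__(self):
        canonicals = [e.tg263_name for e in self.entries]
        if len(canonicals) != len(set(canonicals)):
            raise ConfigurationError("duplicate canonical names in lexicon")
        seen = {}
        for e in self.entries:
            for syn in e.synonyms:
                key = normalize_label(syn)
                if key in seen and seen[key] != e.tg263_name:
                    raise ConfigurationError(
                        f"synonym '{syn}' maps to both {seen[key]} and {e.tg263_name}"
                    )
                seen[key] = e.tg263_name


def normalize_label(raw: str) -> str:
    """Canonicalize a structure label for matching.

    Lowercase; runs of non-alphanumeric characters collapse to single spaces;
    leading/trailing separators are stripped; laterality tokens (lt/left/l,
    rt/right/r) canonicalize to single-letter tokens. Boundaries between
    letters and digits also separate tokens, so "LT_lung" and "LtLung2" both
    tokenize cleanly.
    """
    s = raw.lower()
    s = re.sub(r"[^a-z0-9]+", " ", s)
    s = re.sub(r"(?<=[a-z])(?=[0-9])|(?<=[0-9])(?=[a-z])", " ", s)
    tokens = [_LATERALITY.get(t, t) for t in s.split()]
    return " ".join(tokens)


def load_lexicon(path=None) -> Lexicon:
    """Load a lexicon JSON file; with no path, the bundled starter lexicon."""
    if path is None:
        text = resources.files("rtqa.data").joinpath("tg263_lexicon.json").read_text()
    else:
        with open(path) as fh:
            text = fh.read()
    doc = json.loads(text)
    entries = [
        LexiconEntry(
            tg263_name=e["tg263_name"],
            category=e.get("category", "OAR"),
            synonyms=list(e.get("synonyms", [])),
        )
        for e in doc["entries"]
    ]
    return Lexicon(entries=entries, version=doc.get("version", ""))


def similarity(a: str, b: str) -> float:
    """Normalized edit similarity: 1 - editdistance / max(len)."""
    if not a and not b:
        return 1.0
    if not a or not b:
        return 0.0
    dist = edlib.align(a, b, task="distance")["editDistance"]
    return 1.0 - dist / max(len(a), len(b))


def suggest(raw: str, lexicon: Lexicon, k: int = 5,
            threshold: float = 0.70) -> list:
    """Ranked TG-263 suggestions for a raw structure name.

    Exact matches (normalized raw equals normalized canonical) and synonym
    matches score 1.0 and come first; otherwise the top-k fuzzy candidates by
    normalized edit similarity at or above ``threshold``, descending score,
    ties broken alphabetically by canonical name.
    """
    if k < 1:
        raise ConfigurationError("k must be >= 1")
    if not (0 <= threshold <= 1):
        raise ConfigurationError("threshold must be in [0, 1]")
    if not lexicon.entries:
        raise ConfigurationError("empty lexicon")

    q = normalize_label(raw)
    exact = []
    synonym = []
    fuzzy = {}
    for entry in lexicon.entries:
        canon_norm = normalize_label(entry.tg263_name)
        if q and q == canon_norm:
            exact.append(entry.tg263_name)
            continue
        if q and any(q == normalize_label(s) for s in entry.synonyms):
            synonym.append(entry.tg263_name)
            continue
        score = max(
            [similarity(q, canon_norm)]
            + [similarity(q, normalize_label(s)) for s in entry.synonyms]
        )
        if score >= threshold:
            fuzzy[entry.tg263_name] = score

    out = [Suggestion(n, 1.0, MatchKind.EXACT) for n in sorted(exact)]
    out += [Suggestion(n, 1.0, MatchKind.SYNONYM) for n in sorted(synonym)]
    ranked = sorted(fuzzy.items(), key=lambda kv: (-kv[1], kv[0]))
    out += [Suggestion(n, s, MatchKind.FUZZY) for n, s in ranked]
    return out[:k]


def apply_mapping(ss: StructureSet, mapping: dict) -> StructureSet:
    """Rename structures per ``mapping`` (raw name -> TG-263 name).

    Unmapped structures are retained and flagged ``nonstandard``. Two raw
    names mapping to one canonical is a conflict (merging is not supported);
    output names must be unique.
    """
    present = set(ss.names())
    for raw in mapping:
        if raw not in present:
            raise RtqaError(f"mapped raw name '{raw}' not present in structure set")
    by_canonical: dict = {}
    for raw, canon in mapping.items():
        by_canonical.setdefault(canon, []).append(raw)
    for canon, raws in by_canonical.items():
        if len(raws) > 1:
            raise MappingConflictError(canon, raws)

    new_structures = []
    for s in ss.structures:
        if s.name in mapping:
            new_structures.append(
                replace(s, name=mapping[s.name], nonstandard=False)
            )
        else:
            new_structures.append(replace(s, nonstandard=True))
    out = StructureSet(
        structures=new_structures,
        frame_of_reference=ss.frame_of_reference,
        patient_id=ss.patient_id,
    )
    names = out.names()
    if len(names) != len(set(names)):
        dupes = sorted({n for n in names if names.count(n) > 1})
        raise MappingConflictError(dupes[0], [n for n in names if n in dupes])
    return out
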