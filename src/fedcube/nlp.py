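"""Deterministic clinical-text symptom extraction.

A dictionary matcher finds symptom surface forms in note text (longest
match wins, word boundaries, case-insensitive) and a NegEx-style rule stage
assigns polarity: a mention is negated when a trigger cue ("no", "denies",
"without", "negative for", ...) occurs within a token window before it — or
a post-cue within the window after — with the scope cut off by conjunctions
("but", "however") and sentence boundaries.  The output is structured
symptom records; no raw note text is ever copied forward, so nothing
identifiable survives this stage.

The cue list and window are configuration, not claims about any particular
learned negation model; they are meant to be swapped out module-wise.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from fedcube.errors import ConfigurationError, ValidationError
from fedcube.fhir_io import ResourceRecord


@dataclass(frozen=True)
class SymptomEntry:
    code: str
    label: str
    surface_forms: tuple[str, ...]
    system: str = "ICD-10-CM"


@dataclass
class SymptomDictionary:
    """Concept codes with their recognised lowercase surface forms."""

    entries: list[SymptomEntry]

    def __post_init__(self) -> None:
        seen: dict[str, str] = {}
        for e in self.entries:
            if not e.surface_forms:
                raise ConfigurationError(f"concept {e.code} has no surface forms")
            for f in e.surface_forms:
                if not f or f != f.lower():
                    raise ConfigurationError(f"surface form must be non-empty lowercase: {f!r}")
                if f in seen:
                    raise ConfigurationError(f"surface form {f!r} registered for both {seen[f]} and {e.code}")
                seen[f] = e.code
        self._form_to_code = seen
        self._label_to_entry = {e.label: e for e in self.entries}
        # precompiled word-boundary patterns, one per surface form
        self._patterns = []
        for form, code in seen.items():
            escaped = re.escape(form).replace("\\ ", " ").replace(" ", r"\s+")
            self._patterns.append(
                (re.compile(r"(?<!\w)" + escaped + r"(?!\w)", re.IGNORECASE), code))

    def code_for_label(self, label: str) -> str | None:
        e = self._label_to_entry.get(label)
        return e.code if e else None

    def forms_for_label(self, label: str) -> tuple[str, ...]:
        return self._label_to_entry[label].surface_forms

    @property
    def codes(self) -> list[str]:
        return [e.code for e in self.entries]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SymptomDictionary":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls._from_raw(raw)

    @classmethod
    def _from_raw(cls, raw: list[dict]) -> "SymptomDictionary":
        return cls([
            SymptomEntry(
                code=d["code"],
                label=d["label"],
                surface_forms=tuple(d["surface_forms"]),
                system=d.get("system", "ICD-10-CM"),
            )
            for d in raw
        ])


def load_default_dictionary() -> SymptomDictionary:
    """The shipped five-symptom value set (fever, chills, cough, dyspnea, headache)."""
    raw = yaml.safe_load(resources.files("fedcube.data").joinpath("symptoms.yaml").read_text())
    return SymptomDictionary._from_raw(raw)


@dataclass
class NegationCues:
    pre_cues: list[str]
    post_cues: list[str]
    scope_terminators: list[str]
    window: int = 5

    @classmethod
    def from_yaml(cls, path: str | Path) -> "NegationCues":
        with open(path, "r", encoding="utf-8") as fh:
            return cls(**yaml.safe_load(fh))


def load_default_cues() -> NegationCues:
    raw = yaml.safe_load(resources.files("fedcube.data").joinpath("negation_cues.yaml").read_text())
    return NegationCues(**raw)


@dataclass
class SymptomMention:
    """One matched surface form: [start, end) offsets into the note text."""

    document_id: str
    concept_code: str
    start: int
    end: int
    matched_text: str
    polarity: str | None = None  # "affirmed" | "negated" once classified
    encounter_ref: str | None = None


def extract_mentions(text: str, dictionary: SymptomDictionary) -> list[SymptomMention]:
    """All non-overlapping leftmost-longest dictionary matches at word boundaries.

    Deterministic: candidates are collected for every surface form, then
    selected left to right preferring the longest match at each position;
    output is ordered by span start.
    """
    if not dictionary.entries:
        raise ConfigurationError("symptom dictionary is empty")
    candidates: list[tuple[int, int, str, str]] = []
    for pattern, code in dictionary._patterns:
        for m in pattern.finditer(text):
            candidates.append((m.start(), m.end(), code, m.group(0)))
    candidates.sort(key=lambda c: (c[0], -(c[1] - c[0])))
    mentions: list[SymptomMention] = []
    last_end = 0
    for start, end, code, matched in candidates:
        if start >= last_end:
            mentions.append(SymptomMention("", code, start, end, matched))
            last_end = end
    return mentions


_TOKEN_RE = re.compile(r"\w+|[^\w\s]")
_SENTENCE_ENDERS = {".", ";", "!", "?", ":"}


def detect_negation(text: str, mention: SymptomMention, cues: NegationCues | None = None) -> str:
    """Classify one mention as ``"affirmed"`` or ``"negated"``.

    Scans up to ``cues.window`` tokens before the mention for a pre-cue and
    after it for a post-cue; a scope terminator or sentence boundary between
    cue and mention blocks the negation.
    """
    cues = cues or load_default_cues()
    if not (0 <= mention.start < mention.end <= len(text)):
        raise ValidationError(f"mention span [{mention.start},{mention.end}) outside text")
    tokens = [(m.group(0).lower(), m.start(), m.end()) for m in _TOKEN_RE.finditer(text)]
    first = next((i for i, (_, s, e) in enumerate(tokens) if s <= mention.start < e), None)
    last = next((i for i, (_, s, e) in enumerate(tokens) if s < mention.end <= e), first)
    if first is None:
        return "affirmed"

    def blocked(word: str) -> bool:
        return word in cues.scope_terminators or word in _SENTENCE_ENDERS

    # pre-window: walk backwards, stop at terminator/sentence boundary
    pre: list[str] = []
    for i in range(first - 1, max(-1, first - 1 - cues.window), -1):
        word = tokens[i][0]
        if blocked(word):
            break
        pre.append(word)
    pre.reverse()
    if _contains_phrase(pre, cues.pre_cues):
        return "negated"

    post: list[str] = []
    for i in range(last + 1, min(len(tokens), last + 1 + cues.window)):
        word = tokens[i][0]
        if blocked(word):
            break
        post.append(word)
    if _contains_phrase(post, cues.post_cues):
        return "negated"
    return "affirmed"


def _contains_phrase(words: list[str], phrases: list[str]) -> bool:
    for phrase in phrases:
        parts = phrase.split()
        n = len(parts)
        for i in range(len(words) - n + 1):
            if words[i:i + n] == parts:
                return True
    return False


def classify_mentions(
    text: str, dictionary: SymptomDictionary, cues: NegationCues | None = None
) -> list[SymptomMention]:
    """Extract and polarity-classify every mention in one pass."""
    cues = cues or load_default_cues()
    mentions = extract_mentions(text, dictionary)
    for m in mentions:
        m.polarity = detect_negation(text, m, cues)
    return mentions


def mentions_to_records(mentions: list[SymptomMention], doc: ResourceRecord) -> list[ResourceRecord]:
    """Emit one structured symptom record per *affirmed* mention.

    Records carry the concept code, the source document's encounter
    reference, and the document month — never a span of the note text.
    """
    if doc.resource_type != "DocumentReference":
        raise ValidationError(f"expected DocumentReference, got {doc.resource_type}")
    enc_refs = doc.body.get("context", {}).get("encounter", [])
    enc_ref = enc_refs[0].get("reference") if enc_refs else None
    subject = doc.body.get("subject", {}).get("reference")
    month = (doc.body.get("date") or "")[:7] or None
    out = []
    for k, m in enumerate(mentions):
        if m.polarity != "affirmed":
            continue
        rid = f"nlp-{doc.id}-{m.concept_code}-{k}"
        body = {
            "resourceType": "Observation",
            "id": rid,
            "meta": {"tag": [{"system": "fedcube/source", "code": "nlp"}]},
            "code": {"coding": [{"system": "http://hl7.org/fhir/sid/icd-10-cm",
                                 "code": m.concept_code}]},
            "valueBoolean": True,
        }
        if subject:
            body["subject"] = {"reference": subject}
        if enc_ref:
            body["encounter"] = {"reference": enc_ref}
        if month:
            body["effectiveDateTime"] = month
        out.append(ResourceRecord("Observation", rid, body))
    return out
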