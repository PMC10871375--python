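"""De-identification of FHIR resources before anything leaves the site.

Two mechanisms, applied together by :func:`apply_deid`:

* **Allow-list field rules** (:class:`DeidRules`): every field of a resource
  is dropped unless a rule says otherwise (``keep``,
  ``generalize_date_to_month``, or ``pseudonymize``).  Default-drop is
  fail-safe: a field the rule author never anticipated cannot leak.
* **Keyed codebook** (:class:`Codebook`): identifiers are replaced by a
  deterministic keyed one-way pseudonym (HMAC-SHA256, truncated), so the
  same patient maps to the same pseudonym everywhere — joins survive —
  while no PHI-bearing mapping table ever exists on disk.  The in-memory
  cache exists only to detect (astronomically unlikely) collisions.

Resource types mapped to an empty rule set are dropped entirely; the
shipped template does this for DocumentReference, because note bodies are
consumed by the NLP stage and never cross the site boundary.
"""

from __future__ import annotations

import hmac
import hashlib
import re
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import yaml

from fedcube.errors import ConfigurationError, ValidationError
from fedcube.fhir_io import ResourceRecord

ACTIONS = ("drop", "keep", "generalize_date_to_month", "pseudonymize")

_DATE_RE = re.compile(r"^\d{4}-\d{2}(-\d{2})?([T ].*)?$")


@dataclass
class DeidRules:
    """Per-resource-type field actions with allow-list (default drop) semantics."""

    resources: dict[str, dict[str, str]]
    default_action: str = "drop"

    def __post_init__(self) -> None:
        if self.default_action != "drop":
            raise ConfigurationError("default action must be 'drop' (allow-list semantics)")
        for rtype, fields in self.resources.items():
            for f, action in (fields or {}).items():
                if action not in ACTIONS:
                    raise ConfigurationError(f"{rtype}.{f}: unknown action {action!r}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "DeidRules":
        with open(path, "r", encoding="utf-8") as fh:
            raw = yaml.safe_load(fh)
        return cls(resources={k: (v or {}) for k, v in raw["resources"].items()},
                   default_action=raw.get("default_action", "drop"))


def load_default_rules() -> DeidRules:
    """The shipped reviewed rule template."""
    raw = yaml.safe_load(resources.files("fedcube.data").joinpath("deid_rules.yaml").read_text())
    return DeidRules(resources={k: (v or {}) for k, v in raw["resources"].items()},
                     default_action=raw.get("default_action", "drop"))


@dataclass
class Codebook:
    """Keyed deterministic pseudonymization of identifiers."""

    secret: str
    algorithm: str = "hmac-sha256-16"
    _issued: dict[str, str] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self.secret:
            raise ConfigurationError("codebook secret is missing or empty")


def pseudonymize(identifier: str, codebook: Codebook) -> str:
    """Fixed-length keyed pseudonym; same (secret, input) always maps the same."""
    if not identifier:
        raise ValidationError("cannot pseudonymize an empty identifier")
    if not codebook.secret:
        raise ConfigurationError("codebook secret is missing or empty")
    digest = hmac.new(codebook.secret.encode("utf-8"), identifier.encode("utf-8"),
                      hashlib.sha256).hexdigest()[:16]
    prior = codebook._issued.get(digest)
    if prior is not None and prior != identifier:
        raise ValidationError(f"codebook collision between {prior!r} and {identifier!r}")
    codebook._issued[digest] = identifier
    return digest


def _pseudonymize_reference(ref: str, codebook: Codebook) -> str:
    """'Patient/123' -> 'Patient/<pseudonym of Patient/123>' so joins survive."""
    if "/" in ref:
        rtype, _ = ref.split("/", 1)
        return f"{rtype}/{pseudonymize(ref, codebook)}"
    return pseudonymize(ref, codebook)


def _truncate_to_month(value):
    if isinstance(value, str) and _DATE_RE.match(value):
        return value[:7]
    if isinstance(value, dict):
        return {k: _truncate_to_month(v) for k, v in value.items()}
    return value


def apply_deid(
    record: ResourceRecord, rules: DeidRules, codebook: Codebook
) -> ResourceRecord | None:
    """Apply the field rules to one resource.

    Returns the de-identified record, or ``None`` when the resource type is
    mapped to an empty rule set (drop the whole resource).  Raises for a
    resource type the rules do not cover at all.
    """
    if record.resource_type not in rules.resources:
        raise ValidationError(f"de-identification rules do not cover resource type "
                              f"{record.resource_type!r}")
    field_rules = rules.resources[record.resource_type]
    if not field_rules:
        return None
    out: dict = {"resourceType": record.resource_type}
    for fname, value in record.body.items():
        if fname == "resourceType":
            continue
        action = field_rules.get(fname, rules.default_action)
        if action == "drop":
            continue
        if action == "keep":
            out[fname] = value
        elif action == "generalize_date_to_month":
            out[fname] = _truncate_to_month(value)
        elif action == "pseudonymize":
            if fname == "id":
                out[fname] = pseudonymize(f"{record.resource_type}/{value}", codebook)
            elif isinstance(value, dict) and "reference" in value:
                out[fname] = {"reference": _pseudonymize_reference(value["reference"], codebook)}
            elif isinstance(value, str):
                out[fname] = pseudonymize(value, codebook)
            else:
                raise ValidationError(
                    f"{record.resource_type}.{fname}: cannot pseudonymize value of type "
                    f"{type(value).__name__}")
    return ResourceRecord(record.resource_type, out["id"], out)


def deidentify_export(records_by_type: dict[str, list[ResourceRecord]],
                      rules: DeidRules, codebook: Codebook) -> dict[str, list[ResourceRecord]]:
    """Apply :func:`apply_deid` across a whole export; dropped types vanish."""
    out: dict[str, list[ResourceRecord]] = {}
    for rtype, records in records_by_type.items():
        kept = []
        for rec in records:
            deid = apply_deid(rec, rules, codebook)
            if deid is not None:
                kept.append(deid)
        if kept:
            out[rtype] = kept
    return out
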