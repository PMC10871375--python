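"""Read and write bulk-FHIR NDJSON exports.

Bulk FHIR Data Access delivers one resource per line as newline-delimited
JSON, one file per resource type (``Patient.ndjson``, ``Encounter.ndjson``,
...).  This module provides the minimal reader/writer the pipeline needs,
plus resolution of clinical-note text from ``DocumentReference`` resources
(inline base64 content or a relative file attachment, plain text or HTML).
"""

from __future__ import annotations

import base64
import html
import json
import logging
import re
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path

from fedcube.errors import (
    ParseError,
    ResolutionError,
    UnsupportedFormatError,
    ValidationError,
)

logger = logging.getLogger(__name__)

RESOURCE_TYPES = (
    "Patient",
    "Encounter",
    "Condition",
    "Observation",
    "DocumentReference",
    "MedicationRequest",
)


@dataclass
class ResourceRecord:
    """A single raw FHIR resource as a generic nested record."""

    resource_type: str
    id: str
    body: dict

    def __post_init__(self) -> None:
        if self.resource_type not in RESOURCE_TYPES:
            raise ValidationError(f"unknown resource type: {self.resource_type!r}")
        declared = self.body.get("resourceType")
        if declared != self.resource_type:
            raise ValidationError(
                f"body declares resourceType={declared!r}, expected {self.resource_type!r}"
            )
        if not self.id:
            raise ValidationError("resource id must be non-empty")

    @classmethod
    def from_body(cls, body: dict) -> "ResourceRecord":
        return cls(resource_type=body.get("resourceType", ""), id=body.get("id", ""), body=body)


@dataclass
class BulkExport:
    """One site's export: records grouped by resource type plus provenance."""

    records: dict[str, list[ResourceRecord]] = field(default_factory=dict)
    source_site: str = "site"
    export_time: str = field(default_factory=lambda: datetime(2021, 1, 1).isoformat())

    def of_type(self, resource_type: str) -> list[ResourceRecord]:
        return self.records.get(resource_type, [])


def read_ndjson(path: str | Path, resource_type: str) -> list[ResourceRecord]:
    """Read one NDJSON file into records, preserving file order.

    Each non-empty line must be a well-formed JSON object whose declared
    ``resourceType`` matches *resource_type*; a mismatch is rejected (with the
    line number) rather than silently skipped, so a mis-labelled export file
    cannot corrupt downstream tables.  Blank lines are ignored with a warning.
    """
    path = Path(path)
    if resource_type not in RESOURCE_TYPES:
        raise ValidationError(f"unknown resource type: {resource_type!r}")
    records: list[ResourceRecord] = []
    with path.open("r", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line:
                logger.warning("%s: blank line %d ignored", path, lineno)
                continue
            try:
                body = json.loads(line)
            except json.JSONDecodeError as exc:
                raise ParseError(f"{path}: malformed JSON at line {lineno}: {exc}") from exc
            declared = body.get("resourceType")
            if declared != resource_type:
                raise ValidationError(
                    f"{path}: line {lineno} declares resourceType={declared!r}, "
                    f"expected {resource_type!r}"
                )
            records.append(ResourceRecord(resource_type=resource_type, id=body.get("id", ""), body=body))
    return records


def write_ndjson(records: list[ResourceRecord], path: str | Path) -> Path:
    """Write records of one resource type as NDJSON; round-trips losslessly."""
    path = Path(path)
    types = {r.resource_type for r in records}
    if len(types) > 1:
        raise ValidationError(f"records of mixed types cannot share one file: {sorted(types)}")
    path.parent.mkdir(parents=True, exist_ok=True)
    with path.open("w", encoding="utf-8") as fh:
        for rec in records:
            fh.write(json.dumps(rec.body, sort_keys=True, separators=(",", ":")))
            fh.write("\n")
    return path


_TAG_RE = re.compile(r"<[^>]+>")
_WS_RE = re.compile(r"\s+")


def _html_to_text(markup: str) -> str:
    """Strip tags and collapse whitespace; standard named entities only."""
    text = _TAG_RE.sub(" ", markup)
    text = html.unescape(text)
    return _WS_RE.sub(" ", text).strip()


def resolve_note_text(doc: ResourceRecord, export_dir: str | Path | None = None) -> str:
    """Return the plain text of a clinical note referenced by a DocumentReference.

    Resolution order: inline base64 ``attachment.data`` first, then a relative
    ``attachment.url`` file inside *export_dir*.  HTML content is tag-stripped
    to text.  PDF and other formats raise :class:`UnsupportedFormatError`.
    """
    if doc.resource_type != "DocumentReference":
        raise ValidationError(f"expected DocumentReference, got {doc.resource_type}")
    contents = doc.body.get("content", [])
    if not contents:
        raise ResolutionError(f"DocumentReference/{doc.id} has no content entries")
    attachment = contents[0].get("attachment", {})
    ctype = attachment.get("contentType", "text/plain").split(";")[0].strip().lower()
    if ctype not in ("text/plain", "text/html"):
        raise UnsupportedFormatError(
            f"DocumentReference/{doc.id}: unsupported note format {ctype!r} "
            "(only text/plain and text/html are handled)"
        )
    if "data" in attachment:
        raw = base64.b64decode(attachment["data"]).decode("utf-8")
    elif "url" in attachment:
        if export_dir is None:
            raise ResolutionError(
                f"DocumentReference/{doc.id} references a file but no export directory was given"
            )
        note_path = Path(export_dir) / attachment["url"]
        if not note_path.exists():
            raise ResolutionError(f"DocumentReference/{doc.id}: attachment file {note_path} missing")
        raw = note_path.read_text(encoding="utf-8")
    else:
        raise ResolutionError(f"DocumentReference/{doc.id}: attachment has neither data nor url")
    if ctype == "text/html":
        return _html_to_text(raw)
    return raw


def read_export(site_dir: str | Path, source_site: str | None = None) -> BulkExport:
    """Read a whole site directory (six NDJSON files, missing ones are empty)."""
    site_dir = Path(site_dir)
    if not site_dir.is_dir():
        raise ResolutionError(f"export directory not found: {site_dir}")
    records = {}
    for rtype in RESOURCE_TYPES:
        f = site_dir / f"{rtype}.ndjson"
        records[rtype] = read_ndjson(f, rtype) if f.exists() else []
    return BulkExport(records=records, source_site=source_site or site_dir.name)


def write_export(export: BulkExport, site_dir: str | Path) -> Path:
    """Write a BulkExport as the standard one-file-per-type directory layout."""
    site_dir = Path(site_dir)
    site_dir.mkdir(parents=True, exist_ok=True)
    for rtype in RESOURCE_TYPES:
        write_ndjson(export.of_type(rtype), site_dir / f"{rtype}.ndjson")
    return site_dir
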