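"""Lossless reader/writer for GEO's line-oriented SOFT family-file dialect.

SOFT ("Simple Omnibus Format in Text") serializes GEO's three entity kinds
(samples/GSM, series/GSE, platforms/GPL) as plain text.  Lines beginning with
``^`` open a new entity, ``!`` lines carry attributes as ``field = value``
pairs split at the *first* ``=``, ``#`` lines describe data-table columns, and
rows between the ``table_begin``/``table_end`` attribute markers form a
rectangular data table.

The parsed representation is an ordered item stream per entity, so that
``parse → write → parse`` is an identity: attribute order and multiplicity
(repeated fields such as ``supplementary_file`` or ``characteristics_ch1``)
are preserved exactly, and undocumented fields are kept verbatim rather than
rejected.
"""

from __future__ import annotations

import gzip
import logging
import re
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Iterable, Optional, Union

import yaml

logger = logging.getLogger(__name__)

__all__ = [
    "SoftParseError",
    "SoftAttribute",
    "ColumnDef",
    "TableRow",
    "SoftEntity",
    "SoftDocument",
    "GsmRecord",
    "GplRecord",
    "parse_soft",
    "write_soft",
    "read_soft",
    "write_soft_file",
    "to_structured_export",
    "canonical_field_name",
    "extract_gsm",
    "extract_gpl",
    "parse_soft_date",
]

ENTITY_KINDS = ("SAMPLE", "SERIES", "PLATFORM")

MICROARRAY = "microarray"
RNASEQ = "rnaseq"
UNKNOWN = "unknown"


class SoftParseError(ValueError):
    """Structural error in a SOFT document (bad line grammar, open table...)."""

    def __init__(self, message: str, line_no: Optional[int] = None):
        self.line_no = line_no
        if line_no is not None:
            message = f"line {line_no}: {message}"
        super().__init__(message)


_ENTITY_PREFIX_RE = {
    "SAMPLE": re.compile(r"^sample_", re.IGNORECASE),
    "SERIES": re.compile(r"^series_", re.IGNORECASE),
    "PLATFORM": re.compile(r"^platform_", re.IGNORECASE),
}


def canonical_field_name(raw_key: str, entity_kind: str) -> str:
    """Strip the entity prefix (``Sample_``/``Series_``/``Platform_``) and
    lower-case the remainder.

    Only the prefix matching *entity_kind* is stripped (repeatedly, so the
    mapping is idempotent for any input), which keeps cross-entity names
    intact: ``Sample_series_id`` -> ``series_id`` -> ``series_id``.
    """
    pattern = _ENTITY_PREFIX_RE.get(entity_kind.upper())
    name = raw_key.strip()
    if pattern is not None:
        while pattern.match(name):
            name = pattern.sub("", name, count=1)
    return name.lower()


@dataclass(frozen=True)
class SoftAttribute:
    """One ``!`` line: key as written (without ``!``) plus its value.

    ``has_value`` distinguishes ``!Sample_table_begin`` (bare marker) from
    ``!Sample_foo = `` (explicit empty value) so writing is lossless.
    """

    raw_key: str
    value: str = ""
    has_value: bool = True


@dataclass(frozen=True)
class ColumnDef:
    """One ``#`` line describing a data-table column."""

    text: str


@dataclass(frozen=True)
class TableRow:
    """One raw data row between table_begin and table_end."""

    text: str


Item = Union[SoftAttribute, ColumnDef, TableRow]


@dataclass
class SoftEntity:
    entity_kind: str
    accession: str
    items: list = field(default_factory=list)

    # -- views -------------------------------------------------------------
    @property
    def attributes(self) -> list:
        return [it for it in self.items if isinstance(it, SoftAttribute)]

    @property
    def table_rows(self) -> list:
        return [it.text for it in self.items if isinstance(it, TableRow)]

    @property
    def column_defs(self) -> list:
        return [it.text for it in self.items if isinstance(it, ColumnDef)]

    @property
    def has_table(self) -> bool:
        return any(
            self.canonical_name(a.raw_key) == "table_begin" for a in self.attributes
        )

    def canonical_name(self, raw_key: str) -> str:
        return canonical_field_name(raw_key, self.entity_kind)

    def field_names(self) -> list:
        """Canonical attribute names in order of first appearance."""
        seen: dict = {}
        for a in self.attributes:
            seen.setdefault(self.canonical_name(a.raw_key), None)
        return list(seen)

    def get_all(self, name: str) -> list:
        """All values whose canonical field name equals *name*."""
        name = name.lower()
        return [
            a.value
            for a in self.attributes
            if self.canonical_name(a.raw_key) == name
        ]

    def get_first(self, name: str) -> Optional[str]:
        values = self.get_all(name)
        return values[0] if values else None

    def multimap(self) -> dict:
        """Canonical name -> list of values, insertion-ordered."""
        out: dict = {}
        for a in self.attributes:
            out.setdefault(self.canonical_name(a.raw_key), []).append(a.value)
        return out


@dataclass
class SoftDocument:
    entities: list = field(default_factory=list)

    def by_kind(self, kind: str) -> list:
        kind = kind.upper()
        return [e for e in self.entities if e.entity_kind == kind]

    @property
    def samples(self) -> list:
        return self.by_kind("SAMPLE")

    @property
    def platforms(self) -> list:
        return self.by_kind("PLATFORM")

    @property
    def series(self) -> list:
        return self.by_kind("SERIES")


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------


def parse_soft(text: str) -> SoftDocument:
    """Parse SOFT text into a :class:`SoftDocument`.

    Grammar: ``^KIND = ACCESSION`` opens an entity; ``!key = value`` lines are
    attributes split at the first ``=`` with surrounding whitespace trimmed;
    ``#`` lines are table column descriptions; any other non-blank line is a
    table data row and must fall between ``table_begin`` and ``table_end``.

    Raises :class:`SoftParseError` on attribute/table content before any
    ``^`` line, on a ``table_begin`` left open, and on stray data rows.
    """
    doc = SoftDocument()
    current: Optional[SoftEntity] = None
    in_table = False

    for line_no, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        lead = line[0]
        if lead == "^":
            if in_table:
                raise SoftParseError("table_begin without table_end", line_no)
            body = line[1:]
            if "=" in body:
                kind_part, acc_part = body.split("=", 1)
            else:
                kind_part, acc_part = body, ""
            kind = kind_part.strip().upper()
            accession = acc_part.strip()
            if not kind:
                raise SoftParseError("entity line without a kind", line_no)
            if not accession:
                raise SoftParseError("entity line without an accession", line_no)
            current = SoftEntity(entity_kind=kind, accession=accession)
            doc.entities.append(current)
        elif lead == "!":
            if current is None:
                raise SoftParseError("attribute line before any '^' entity", line_no)
            body = line[1:]
            if "=" in body:
                key_part, value_part = body.split("=", 1)
                attr = SoftAttribute(
                    raw_key=key_part.strip(), value=value_part.strip(), has_value=True
                )
            else:
                attr = SoftAttribute(raw_key=body.strip(), value="", has_value=False)
            canon = current.canonical_name(attr.raw_key)
            if canon == "table_begin":
                if in_table:
                    raise SoftParseError("nested table_begin", line_no)
                in_table = True
            elif canon == "table_end":
                if not in_table:
                    raise SoftParseError("table_end without table_begin", line_no)
                in_table = False
            current.items.append(attr)
        elif lead == "#":
            if current is None:
                raise SoftParseError("column line before any '^' entity", line_no)
            current.items.append(ColumnDef(line[1:]))
        else:
            if current is None or not in_table:
                raise SoftParseError("data row outside a table", line_no)
            current.items.append(TableRow(line))

    if in_table:
        raise SoftParseError("table_begin without table_end at end of input")
    return doc


# ---------------------------------------------------------------------------
# writing
# ---------------------------------------------------------------------------


def write_soft(doc: SoftDocument) -> str:
    """Serialize a document back to SOFT text.

    Output is accepted by :func:`parse_soft` and bit-exact under a second
    round trip (the writer normalizes spacing around ``=``).
    """
    lines: list = []
    for entity in doc.entities:
        lines.append(f"^{entity.entity_kind} = {entity.accession}")
        for item in entity.items:
            if isinstance(item, SoftAttribute):
                if item.has_value:
                    lines.append(f"!{item.raw_key} = {item.value}")
                else:
                    lines.append(f"!{item.raw_key}")
            elif isinstance(item, ColumnDef):
                lines.append(f"#{item.text}")
            else:
                lines.append(item.text)
    if not lines:
        return ""
    return "\n".join(lines) + "\n"


def read_soft(path) -> SoftDocument:
    """Read a SOFT file; ``.gz`` suffixed paths are transparently decompressed."""
    path = Path(path)
    if path.suffix == ".gz":
        with gzip.open(path, "rt", encoding="utf-8") as fh:
            return parse_soft(fh.read())
    return parse_soft(path.read_text(encoding="utf-8"))


def write_soft_file(doc: SoftDocument, path) -> None:
    path = Path(path)
    text = write_soft(doc)
    if path.suffix == ".gz":
        with gzip.open(path, "wt", encoding="utf-8") as fh:
            fh.write(text)
    else:
        path.write_text(text, encoding="utf-8")


# ---------------------------------------------------------------------------
# structured (YAML) export
# ---------------------------------------------------------------------------


def to_structured_export(entity: SoftEntity, catalog=None) -> str:
    """Export one entity as a hierarchical YAML document.

    Repeated fields become lists; single occurrences stay scalar.  When a
    field *catalog* (iterable of entries with ``name``/``field_class``) is
    supplied, attributes are grouped under their class (biological, database,
    technical) with unmatched names under ``unknown``.
    """
    mm = entity.multimap()

    def fold(values):
        return values[0] if len(values) == 1 else list(values)

    payload: dict = {
        "accession": entity.accession,
        "entity_kind": entity.entity_kind,
    }
    if catalog is None:
        payload["attributes"] = {name: fold(vals) for name, vals in mm.items()}
    else:
        from .field_catalog import reduce_field_name  # deferred: no cycle at import

        class_of = {e.name.lower(): e.field_class for e in catalog}
        grouped: dict = {}
        for name, vals in mm.items():
            cls = class_of.get(reduce_field_name(name.lower()), "unknown")
            grouped.setdefault(cls, {})[name] = fold(vals)
        payload["attributes"] = grouped
    return yaml.safe_dump(payload, sort_keys=False, allow_unicode=True)


# ---------------------------------------------------------------------------
# record extraction
# ---------------------------------------------------------------------------

_MONTHS = {
    "jan": 1, "feb": 2, "mar": 3, "apr": 4, "may": 5, "jun": 6,
    "jul": 7, "aug": 8, "sep": 9, "oct": 10, "nov": 11, "dec": 12,
}


def parse_soft_date(value: Optional[str]) -> Optional[date]:
    """Parse the SOFT ``Mon DD YYYY`` date convention; None on failure."""
    if not value:
        return None
    parts = value.split()
    if len(parts) != 3:
        return None
    mon, day, year = parts
    month = _MONTHS.get(mon.lower()[:3])
    if month is None:
        return None
    try:
        return date(int(year), month, int(day))
    except ValueError:
        return None


@dataclass
class GsmRecord:
    """Flattened view of one SAMPLE entity, as consumed by the audit stages."""

    accession: str
    channel_count: int = 0
    characteristics: dict = field(default_factory=dict)  # channel -> [raw strings]
    organisms: list = field(default_factory=list)
    taxids: list = field(default_factory=list)
    supplementary_files: list = field(default_factory=list)
    platform_id: Optional[str] = None
    series_ids: list = field(default_factory=list)
    submission_date: Optional[date] = None
    technology_hint: str = UNKNOWN
    field_names: tuple = ()

    def all_characteristics(self) -> list:
        out = []
        for channel in sorted(self.characteristics):
            out.extend(self.characteristics[channel])
        return out


@dataclass
class GplRecord:
    accession: str
    manufacturer: str = ""
    distribution: str = ""
    technology: str = ""
    organism: str = ""


_CHAR_RE = re.compile(r"^characteristics(?:_ch(\d+))?$")
_ORG_RE = re.compile(r"^organism(?:_ch(\d+))?$")
_TAXID_RE = re.compile(r"^taxid(?:_ch(\d+))?$")
_SUPP_RE = re.compile(r"^supplementary_file(?:_\d+)?$")

_RNASEQ_FIELDS = {"library_strategy", "library_source", "library_selection"}
_ARRAY_FIELDS = {"label", "label_protocol", "hyb_protocol", "scan_protocol"}


def _technology_hint(names: set, platform_technology: Optional[str]) -> str:
    """Derive the technology from attribute values only, never the accession."""
    if names & _RNASEQ_FIELDS:
        return RNASEQ
    if platform_technology:
        tech = platform_technology.lower()
        if "sequenc" in tech:
            return RNASEQ
        if "oligonucleotide" in tech or "spotted" in tech or "array" in tech:
            return MICROARRAY
    if names & _ARRAY_FIELDS:
        return MICROARRAY
    return UNKNOWN


def extract_gsm(
    entity: SoftEntity, platform_technology: Optional[str] = None
) -> GsmRecord:
    """Build a :class:`GsmRecord` from a SAMPLE entity.

    *platform_technology* (the linked GPL's ``technology`` attribute) refines
    the technology hint when the sample attributes alone are inconclusive.
    Unparseable submission dates are logged and left as ``None``; such records
    are excluded from growth series downstream.
    """
    if entity.entity_kind != "SAMPLE":
        raise ValueError(f"not a SAMPLE entity: {entity.entity_kind}")
    rec = GsmRecord(accession=entity.accession)
    characteristics: dict = {}
    names_seen: dict = {}
    for attr in entity.attributes:
        name = entity.canonical_name(attr.raw_key)
        names_seen.setdefault(name, None)
        m = _CHAR_RE.match(name)
        if m:
            channel = int(m.group(1)) if m.group(1) else 1
            characteristics.setdefault(channel, []).append(attr.value)
            continue
        m = _ORG_RE.match(name)
        if m:
            if attr.value and attr.value not in rec.organisms:
                rec.organisms.append(attr.value)
            continue
        m = _TAXID_RE.match(name)
        if m:
            if attr.value and attr.value not in rec.taxids:
                rec.taxids.append(attr.value)
            continue
        if _SUPP_RE.match(name):
            if attr.value and attr.value.upper() != "NONE":
                rec.supplementary_files.append(attr.value)
            continue
        if name == "platform_id":
            rec.platform_id = attr.value
        elif name == "series_id":
            for token in attr.value.split(","):
                token = token.strip()
                if token and token not in rec.series_ids:
                    rec.series_ids.append(token)
        elif name == "channel_count":
            try:
                rec.channel_count = int(attr.value)
            except ValueError:
                logger.warning(
                    "%s: non-integer channel_count %r", entity.accession, attr.value
                )
        elif name == "submission_date":
            rec.submission_date = parse_soft_date(attr.value)
            if rec.submission_date is None:
                logger.warning(
                    "%s: unparseable submission_date %r; record excluded "
                    "from growth series",
                    entity.accession,
                    attr.value,
                )
    rec.characteristics = characteristics
    if rec.channel_count == 0 and characteristics:
        rec.channel_count = max(characteristics)
    rec.field_names = tuple(names_seen)
    rec.technology_hint = _technology_hint(set(names_seen), platform_technology)
    return rec


def extract_gpl(entity: SoftEntity) -> GplRecord:
    if entity.entity_kind != "PLATFORM":
        raise ValueError(f"not a PLATFORM entity: {entity.entity_kind}")
    return GplRecord(
        accession=entity.accession,
        manufacturer=entity.get_first("manufacturer") or "",
        distribution=(entity.get_first("distribution") or "").strip().lower(),
        technology=entity.get_first("technology") or "",
        organism=entity.get_first("organism") or "",
    )


def extract_gsms(doc: SoftDocument) -> list:
    """Extract all samples of a document, resolving GPL technology links."""
    gpl_tech = {p.accession: (p.get_first("technology") or "") for p in doc.platforms}
    out = []
    for entity in doc.samples:
        platform_id = entity.get_first("platform_id")
        out.append(extract_gsm(entity, gpl_tech.get(platform_id or "")))
    return out
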