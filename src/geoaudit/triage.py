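"""Reusability triage of microarray GSMs.

Raw microarray intensities live in supplementary files whose usefulness
depends on the file type and on which manufacturer produced the array, so a
GSM is triaged from three signals: its supplementary-file extensions, the
platform's (normalized) manufacturer, and the platform distribution class.

Rules, applied in order:

1. *unrecoverable* — no supplementary files, no manufacturer, only
   nonprocessable file types (.tiff/.tif/.jpg/.jpeg/.xls/.xlsx), or a
   noncommercial distribution;
2. *reusable* — commercial or custom-commercial distribution by one of the
   three automatable manufacturers with a matching file type
   (Affymetrix: .cel, Agilent: .txt, NimbleGen: .xys or .pair);
3. *potentially_reusable* — everything else.

Every result carries the rule that fired, keeping decisions auditable.
"""

from __future__ import annotations

import csv
from collections import Counter
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "NONPROCESSABLE_EXTENSIONS",
    "MANUFACTURER_EXTENSIONS",
    "REUSABLE",
    "POTENTIALLY_REUSABLE",
    "UNRECOVERABLE",
    "SupplementaryFileInfo",
    "ManufacturerInfo",
    "TriageResult",
    "load_alias_table",
    "file_category",
    "normalize_manufacturer",
    "normalize_distribution",
    "triage_gsm",
    "triage_summary",
]

REUSABLE = "reusable"
POTENTIALLY_REUSABLE = "potentially_reusable"
UNRECOVERABLE = "unrecoverable"

PROCESSABLE_CANDIDATE = "processable_candidate"
NONPROCESSABLE = "nonprocessable"
NONE = "none"

#: .tif/.jpeg are folded into the .tiff/.jpg classes.
NONPROCESSABLE_EXTENSIONS = frozenset({"tiff", "tif", "jpg", "jpeg", "xls", "xlsx"})

_COMPRESSION_SUFFIXES = ("gz", "bz2")

#: Standard raw-data extension per automatable manufacturer.
MANUFACTURER_EXTENSIONS = {
    "Affymetrix": frozenset({"cel"}),
    "Agilent": frozenset({"txt"}),
    "NimbleGen": frozenset({"xys", "pair"}),
}

_DISTRIBUTIONS = {
    "commercial": "commercial",
    "custom-commercial": "custom_commercial",
    "custom_commercial": "custom_commercial",
    "custom commercial": "custom_commercial",
    "non-commercial": "noncommercial",
    "noncommercial": "noncommercial",
}


@dataclass(frozen=True)
class SupplementaryFileInfo:
    filename: str
    extension: str
    category: str


@dataclass(frozen=True)
class ManufacturerInfo:
    raw_name: str
    canonical: str  # Affymetrix / Agilent / NimbleGen / other:<name> / none
    distribution: str  # commercial / custom_commercial / noncommercial / unknown


@dataclass(frozen=True)
class TriageResult:
    gsm: str
    label: str
    rule_fired: str


def file_category(filename: str) -> SupplementaryFileInfo:
    """Categorize one supplementary filename from its terminal extension.

    Compression suffixes (.gz, .bz2) are stripped first; the remaining
    terminal suffix is lower-cased.  An absent filename yields category
    ``none``.
    """
    if not filename or not filename.strip():
        return SupplementaryFileInfo(filename or "", "", NONE)
    name = filename.strip().lower().rstrip(".")
    parts = name.split(".")
    while len(parts) > 1 and parts[-1] in _COMPRESSION_SUFFIXES:
        parts.pop()
    extension = parts[-1] if len(parts) > 1 else ""
    category = (
        NONPROCESSABLE if extension in NONPROCESSABLE_EXTENSIONS else PROCESSABLE_CANDIDATE
    )
    return SupplementaryFileInfo(filename, extension, category)


def load_alias_table(path=None) -> dict:
    """Manufacturer alias table, lower-cased raw name -> canonical name."""
    path = (
        Path(path)
        if path is not None
        else Path(resources.files("geoaudit") / "data" / "manufacturer_aliases.tsv")
    )
    aliases: dict = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            aliases[row["raw_name"].strip().lower()] = row["canonical"].strip()
    return aliases


def normalize_distribution(raw: Optional[str]) -> str:
    if not raw:
        return "unknown"
    return _DISTRIBUTIONS.get(raw.strip().lower(), "unknown")


def normalize_manufacturer(
    raw: Optional[str], distribution: Optional[str] = None, aliases: Optional[dict] = None
) -> ManufacturerInfo:
    """Resolve manufacturer name variants to a canonical manufacturer.

    Lookup is case-insensitive on the whitespace-collapsed name against the
    bundled alias table; unmatched non-empty names map to ``other:<cleaned>``,
    empty/absent names to ``none``.
    """
    if aliases is None:
        aliases = load_alias_table()
    dist = normalize_distribution(distribution)
    if raw is None or not raw.strip():
        return ManufacturerInfo(raw or "", NONE, dist)
    cleaned = " ".join(raw.split())
    canonical = aliases.get(cleaned.lower(), f"other:{cleaned}")
    return ManufacturerInfo(raw, canonical, dist)


def triage_gsm(gsm, manufacturer: ManufacturerInfo) -> TriageResult:
    """Apply the triage rules, in order, to one microarray GSM.

    Raises ``ValueError`` when handed an RNA-seq record; records with an
    unknown technology hint are triaged (the caller decides what to feed in).
    """
    if gsm.technology_hint == "rnaseq":
        raise ValueError(f"{gsm.accession}: triage is defined for microarray GSMs only")
    files = [file_category(f) for f in gsm.supplementary_files]
    files = [f for f in files if f.category != NONE]

    if not files:
        return TriageResult(gsm.accession, UNRECOVERABLE, "no_supplementary_files")
    if manufacturer.canonical == NONE:
        return TriageResult(gsm.accession, UNRECOVERABLE, "no_manufacturer")
    if all(f.category == NONPROCESSABLE for f in files):
        return TriageResult(gsm.accession, UNRECOVERABLE, "all_files_nonprocessable")
    if manufacturer.distribution == "noncommercial":
        return TriageResult(gsm.accession, UNRECOVERABLE, "noncommercial_distribution")

    if manufacturer.distribution in ("commercial", "custom_commercial"):
        expected = MANUFACTURER_EXTENSIONS.get(manufacturer.canonical)
        if expected and any(f.extension in expected for f in files):
            return TriageResult(
                gsm.accession,
                REUSABLE,
                f"manufacturer_extension_match:{manufacturer.canonical}",
            )
    return TriageResult(gsm.accession, POTENTIALLY_REUSABLE, "default")


def triage_summary(
    results: Iterable,
    by: str = "overall",
    manufacturer_of: Optional[dict] = None,
) -> pd.DataFrame:
    """Counts and fractions per label, overall or per manufacturer.

    ``manufacturer_of`` maps GSM accession -> canonical manufacturer and is
    required for ``by='manufacturer'``.  Fractions sum to 1 within each group.
    """
    results = list(results)
    if by == "overall":
        groups = {"overall": results}
    elif by == "manufacturer":
        if manufacturer_of is None:
            raise ValueError("by='manufacturer' requires manufacturer_of")
        groups = {}
        for r in results:
            groups.setdefault(manufacturer_of.get(r.gsm, NONE), []).append(r)
    else:
        raise ValueError(f"unknown grouping {by!r}")
    rows = []
    for group in sorted(groups):
        counts = Counter(r.label for r in groups[group])
        total = sum(counts.values())
        for label in (REUSABLE, POTENTIALLY_REUSABLE, UNRECOVERABLE):
            rows.append(
                {
                    "group": group,
                    "label": label,
                    "count": counts.get(label, 0),
                    "fraction": counts.get(label, 0) / total if total else 0.0,
                }
            )
    return pd.DataFrame(rows)
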