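"""Taxonomic labelling of GSMs from their annotated organism(s).

Lookup is against a pluggable lineage table (organism name -> superkingdom /
phylum / species); a small deterministic fixture ships with the package so
the pipeline stays download-free.  GSMs annotated with more than one distinct
organism get the ``multiple_organism`` label; ambiguous special annotations
("synthetic", "chimeric", "environmental sample") get their own categories.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

__all__ = [
    "Lineage",
    "LineageTable",
    "TaxonLabel",
    "load_lineage",
    "assign_label",
    "count_by_rank",
    "SPECIAL_LABELS",
]

MULTIPLE_ORGANISM = "multiple_organism"
SYNTHETIC_CHIMERIC = "synthetic_chimeric"
ENVIRONMENTAL_SAMPLES = "environmental_samples"
UNCLASSIFIED = "unclassified"

SPECIAL_LABELS = (MULTIPLE_ORGANISM, SYNTHETIC_CHIMERIC, ENVIRONMENTAL_SAMPLES, UNCLASSIFIED)

# substring -> label, matched case-insensitively on the organism annotation
_SPECIAL_PATTERNS = (
    ("synthetic", SYNTHETIC_CHIMERIC),
    ("chimeric", SYNTHETIC_CHIMERIC),
    ("environmental sample", ENVIRONMENTAL_SAMPLES),
)


@dataclass(frozen=True)
class Lineage:
    superkingdom: str
    phylum: str
    species: str


class LineageTable:
    """Case-folded organism-name index over lineage rows."""

    def __init__(self, entries: dict):
        for name, lin in entries.items():
            if not lin.superkingdom:
                raise ValueError(f"{name}: empty superkingdom")
        self._entries = {name.casefold(): lin for name, lin in entries.items()}

    def lookup(self, organism: str) -> Optional[Lineage]:
        return self._entries.get(organism.casefold())

    def __len__(self):
        return len(self._entries)

    def __contains__(self, organism: str):
        return organism.casefold() in self._entries


def load_lineage(path=None) -> LineageTable:
    """Load a lineage TSV (organism, superkingdom, phylum, species)."""
    path = (
        Path(path)
        if path is not None
        else Path(resources.files("geoaudit") / "data" / "lineage.tsv")
    )
    entries: dict = {}
    with open(path, newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh, delimiter="\t"):
            entries[row["organism"]] = Lineage(
                row["superkingdom"], row["phylum"], row["species"]
            )
    return LineageTable(entries)


@dataclass(frozen=True)
class TaxonLabel:
    gsm: str
    label: str


def assign_label(gsm, lineage: LineageTable) -> TaxonLabel:
    """Total labelling function: every GSM gets exactly one label."""
    organisms = [o for o in gsm.organisms if o.strip()]
    if len(set(o.casefold() for o in organisms)) > 1:
        return TaxonLabel(gsm.accession, MULTIPLE_ORGANISM)
    if not organisms:
        return TaxonLabel(gsm.accession, UNCLASSIFIED)
    organism = organisms[0]
    low = organism.casefold()
    for pattern, label in _SPECIAL_PATTERNS:
        if pattern in low:
            return TaxonLabel(gsm.accession, label)
    lin = lineage.lookup(organism)
    if lin is None:
        return TaxonLabel(gsm.accession, UNCLASSIFIED)
    return TaxonLabel(gsm.accession, lin.superkingdom)


def count_by_rank(records: Iterable, lineage: LineageTable, rank: str) -> pd.DataFrame:
    """Counts per (rank value, technology).

    ``rank='superkingdom'`` uses the full label assignment (special
    categories included), so the table conserves the corpus size.  For
    ``phylum``/``species`` only single-organism GSMs resolvable in the
    lineage table are counted; everything else rolls into ``unclassified``.
    """
    if rank not in ("superkingdom", "phylum", "species"):
        raise ValueError(f"unknown rank {rank!r}")
    rows = []
    for gsm in records:
        if rank == "superkingdom":
            value = assign_label(gsm, lineage).label
        else:
            label = assign_label(gsm, lineage)
            if label.label in SPECIAL_LABELS:
                value = UNCLASSIFIED if label.label == UNCLASSIFIED else label.label
            else:
                lin = lineage.lookup(gsm.organisms[0])
                value = getattr(lin, rank)
        rows.append({"value": value, "technology": gsm.technology_hint})
    if not rows:
        return pd.DataFrame(columns=["value", "technology", "count"])
    df = pd.DataFrame(rows)
    out = (
        df.groupby(["value", "technology"], as_index=False)
        .size()
        .rename(columns={"size": "count"})
        .sort_values(["value", "technology"], ignore_index=True)
    )
    return out
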