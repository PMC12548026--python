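"""Structuredness audit of the GSM ``characteristics`` field.

The ``characteristics`` attribute is meant to describe the biological source
as ``<tag>: <value>`` pairs.  A GSM counts as *putative structured* at
stringency ``(k_tag, k_value)`` only if **every** one of its pairs splits
into a non-empty tag and value whose word counts stay within the limits;
GSMs with no characteristics content at all are *empty*, everything else is
*not structured*.  On top of the per-GSM classification this module builds
the GSM x tag table, profiles per-column missingness and tag frequency, and
flags strain-like tag redundancy.
"""

from __future__ import annotations

import logging
import math
import re
from dataclasses import dataclass, field
from typing import Iterable, Optional

import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "UNBOUNDED",
    "EMPTY",
    "PUTATIVE_STRUCTURED",
    "NOT_STRUCTURED",
    "CharacteristicsPair",
    "GsmStructureLabel",
    "CharacteristicsTable",
    "parse_characteristics",
    "classify_gsm",
    "stringency_sweep",
    "build_table",
    "tag_frequency",
    "strain_like_tags",
    "canonical_tag",
]

#: Sentinel for "any number of words is allowed".
UNBOUNDED = math.inf

EMPTY = "empty"
PUTATIVE_STRUCTURED = "putative_structured"
NOT_STRUCTURED = "not_structured"


@dataclass(frozen=True)
class CharacteristicsPair:
    raw: str
    tag: Optional[str]
    value: Optional[str]
    tag_words: int
    value_words: int
    parsed: bool


def parse_characteristics(raw: str) -> CharacteristicsPair:
    """Split one characteristics string into a tag/value pair.

    The split point is the first ``": "`` (colon+space) when present,
    otherwise the first ``:``; this keeps colons inside URLs or clock times
    in the value from shadowing the real separator.  Both sides are trimmed;
    a pair is ``parsed`` only if both sides are non-empty.  Word counts are
    counts of maximal non-whitespace runs.  Never raises.
    """
    idx = raw.find(": ")
    if idx == -1:
        idx = raw.find(":")
    if idx == -1:
        return CharacteristicsPair(raw, None, None, 0, 0, False)
    tag = raw[:idx].strip()
    value = raw[idx + 1 :].strip()
    if not tag or not value:
        return CharacteristicsPair(raw, None, None, 0, 0, False)
    return CharacteristicsPair(
        raw, tag, value, len(tag.split()), len(value.split()), True
    )


@dataclass(frozen=True)
class GsmStructureLabel:
    gsm: str
    label: str
    k_tag: float
    k_value: float


def _content_lines(gsm) -> list:
    return [s for s in gsm.all_characteristics() if s.strip()]


def classify_gsm(gsm, k_tag: float = UNBOUNDED, k_value: float = UNBOUNDED):
    """Classify one GSM as empty / putative_structured / not_structured.

    Whitespace-only characteristics lines count as no information.  The
    structured label requires *all* pairs to parse within the word limits.
    """
    if k_tag < 1 or k_value < 1:
        raise ValueError("stringency limits must be >= 1 (or UNBOUNDED)")
    lines = _content_lines(gsm)
    if not lines:
        return GsmStructureLabel(gsm.accession, EMPTY, k_tag, k_value)
    pairs = [parse_characteristics(s) for s in lines]
    ok = all(
        p.parsed and p.tag_words <= k_tag and p.value_words <= k_value for p in pairs
    )
    label = PUTATIVE_STRUCTURED if ok else NOT_STRUCTURED
    return GsmStructureLabel(gsm.accession, label, k_tag, k_value)


def stringency_sweep(gsms: Iterable, k_max: int) -> pd.DataFrame:
    """Count classes for joint stringency k = 1..k_max plus unbounded.

    Returns a DataFrame with columns ``k`` (float, ``inf`` = unbounded),
    ``n_empty``, ``n_structured``, ``n_not_structured``.  ``n_empty`` is
    constant in k and ``n_structured`` is non-decreasing.
    """
    if k_max < 1:
        raise ValueError("k_max must be >= 1")
    n_empty = 0
    profiles = []  # (all_parsed, max_tag_words, max_value_words)
    for gsm in gsms:
        lines = _content_lines(gsm)
        if not lines:
            n_empty += 1
            continue
        pairs = [parse_characteristics(s) for s in lines]
        profiles.append(
            (
                all(p.parsed for p in pairs),
                max(p.tag_words for p in pairs),
                max(p.value_words for p in pairs),
            )
        )
    rows = []
    ks = [float(k) for k in range(1, k_max + 1)] + [UNBOUNDED]
    for k in ks:
        n_structured = sum(
            1 for ok, mt, mv in profiles if ok and mt <= k and mv <= k
        )
        rows.append(
            {
                "k": k,
                "n_empty": n_empty,
                "n_structured": n_structured,
                "n_not_structured": len(profiles) - n_structured,
            }
        )
    return pd.DataFrame(rows)


_WS_RE = re.compile(r"\s+")


def canonical_tag(tag: str) -> str:
    """Case-fold and collapse internal whitespace (column identity only;
    values are never canonicalized)."""
    return _WS_RE.sub(" ", tag.strip()).casefold()


@dataclass
class CharacteristicsTable:
    """GSM x tag matrix built from putative-structured pairs."""

    frame: pd.DataFrame  # rows: GSM accessions; columns: canonical tags; NaN = missing
    collisions: int = 0

    @property
    def column_missing_fraction(self) -> pd.Series:
        n = len(self.frame)
        if n == 0:
            return pd.Series(dtype=float)
        return 1.0 - self.frame.notna().sum() / n

    @property
    def n_nonmissing_cells(self) -> int:
        return int(self.frame.notna().sum().sum())


def build_table(
    gsms: Iterable, k_tag: float = UNBOUNDED, k_value: float = UNBOUNDED
) -> CharacteristicsTable:
    """Assemble the characteristics table from putative-structured GSMs.

    Raises ``ValueError`` if any input is not putative_structured at the
    given stringency.  Duplicate tags within one GSM keep the first value;
    collisions are counted and logged.
    """
    rows: dict = {}
    collisions = 0
    for gsm in gsms:
        label = classify_gsm(gsm, k_tag, k_value)
        if label.label != PUTATIVE_STRUCTURED:
            raise ValueError(
                f"{gsm.accession}: not putative_structured at "
                f"k_tag={k_tag}, k_value={k_value} (got {label.label})"
            )
        cells: dict = {}
        for raw in _content_lines(gsm):
            pair = parse_characteristics(raw)
            col = canonical_tag(pair.tag)
            if col in cells:
                collisions += 1
                logger.warning(
                    "%s: duplicate tag %r, keeping first value", gsm.accession, col
                )
                continue
            cells[col] = pair.value
        rows[gsm.accession] = cells
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.index.name = "gsm"
    return CharacteristicsTable(frame=frame, collisions=collisions)


def tag_frequency(table: CharacteristicsTable) -> list:
    """Ranked ``(tag, pct-of-GSMs)`` list, descending pct, ties lexicographic."""
    n = len(table.frame)
    if n == 0:
        return []
    pcts = (table.frame.notna().sum() / n * 100.0).to_dict()
    return sorted(pcts.items(), key=lambda kv: (-kv[1], kv[0]))


_TOKEN_RE = re.compile(r"[^\W_]+", re.UNICODE)


def strain_like_tags(tags: Iterable) -> tuple:
    """Tags containing the token ``strain`` (word-boundary, punctuation
    stripped), plus their proportion among all tags."""
    tags = set(tags)
    subset = {
        t for t in tags if "strain" in (m.casefold() for m in _TOKEN_RE.findall(t))
    }
    proportion = len(subset) / len(tags) if tags else 0.0
    return subset, proportion
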