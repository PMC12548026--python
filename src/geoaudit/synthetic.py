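"""Synthetic SOFT corpus generator with a ground-truth manifest.

Generates GSM/GPL/GSE family files whose statistical structure matches what
the audit stages assume — characteristics lines with controllable
``<tag>: <value>`` structuredness and word counts, channel-suffixed fields,
supplementary-file lists with mixed extensions, manufacturer/distribution
annotations on platforms, and submission years following configurable growth
curves — together with a manifest recording the intended label of every GSM,
so every pipeline stage can be tested against exact ground truth without
touching GEO.

Randomness is drawn from per-GSM, per-aspect substreams
(``SeedSequence(seed, spawn_key=(gsm_index, aspect))``) so that changing,
say, the supplementary-file mix never perturbs characteristics sampling.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dc_field
from importlib import resources
from pathlib import Path
from shutil import copyfile
from typing import Optional

import numpy as np

from .soft_io import SoftAttribute, SoftDocument, SoftEntity, write_soft
from .taxonomy import load_lineage

__all__ = [
    "CorpusConfig",
    "ConfigError",
    "generate_corpus",
    "write_corpus",
    "generate_reference_fixture",
    "manifest_structure_label",
    "expected_structure_counts",
]


class ConfigError(ValueError):
    pass


# aspect ids for substream isolation
_ASPECT_TECH = 0
_ASPECT_YEAR = 1
_ASPECT_CHAR = 2
_ASPECT_ORG = 3
_ASPECT_SUPP = 4
_ASPECT_GPL = 5
_ASPECT_DATE = 6
_ASPECT_CHANNEL = 7

_MONTH_ABBREV = [
    "Jan", "Feb", "Mar", "Apr", "May", "Jun",
    "Jul", "Aug", "Sep", "Oct", "Nov", "Dec",
]

# colon-free vocabulary for values and unstructured prose
_WORDS = (
    "aerobic anaerobic baseline biofilm broth carbon cells control culture "
    "depletion exponential glucose growth heat induced log medium minimal "
    "mutant nitrogen overnight oxidative phase phosphate replicate rich "
    "sample shock stationary stress treated untreated wildtype"
).split()

_SPECIAL_ORGANISMS = {
    "__multiple__": None,
    "__synthetic__": "synthetic construct",
    "__environmental__": "environmental samples",
}


def _default_technology_mix():
    return {"microarray": 0.48, "rnaseq": 0.52}


def _default_tag_vocabulary():
    return {
        "strain": 0.9,
        "medium": 0.7,
        "growth phase": 0.5,
        "treatment": 0.4,
        "genotype": 0.3,
        "strain background": 0.2,
    }


def _default_manufacturer_mix():
    return [
        {"raw": "Affymetrix, Inc.", "canonical": "Affymetrix",
         "distribution": "commercial", "prob": 0.25},
        {"raw": "Agilent Technologies", "canonical": "Agilent",
         "distribution": "commercial", "prob": 0.20},
        {"raw": "Roche NimbleGen", "canonical": "NimbleGen",
         "distribution": "commercial", "prob": 0.10},
        {"raw": "MYcroarray", "canonical": "other",
         "distribution": "custom_commercial", "prob": 0.15},
        {"raw": "", "canonical": "none", "distribution": "unknown", "prob": 0.10},
        {"raw": "home spotted", "canonical": "other",
         "distribution": "noncommercial", "prob": 0.20},
    ]


def _default_supplementary_mix():
    return {
        "none": 0.17,
        "cel": 0.20,
        "txt": 0.31,
        "pair": 0.05,
        "xys": 0.05,
        "image": 0.07,
        "spreadsheet": 0.05,
        "mixed": 0.10,
    }


def _default_organism_mix():
    return {
        "Escherichia coli": 0.35,
        "Bacillus subtilis": 0.15,
        "Staphylococcus aureus": 0.10,
        "Mycobacterium tuberculosis": 0.10,
        "Pseudomonas aeruginosa": 0.10,
        "Salmonella enterica": 0.07,
        "Haloferax volcanii": 0.03,
        "Saccharomyces cerevisiae": 0.02,
        "__multiple__": 0.04,
        "__synthetic__": 0.02,
        "__environmental__": 0.02,
    }


def _default_growth():
    # microarray records since 2000, RNA-seq since 2009
    return {
        "microarray": {
            "model": "logistic",
            "L": 45293.79,
            "k": 0.3968,
            "x0": 2011.245,
            "year_min": 2000,
            "year_max": 2025,
        },
        "rnaseq": {
            "model": "cubic",
            "coeffs_centered": [7.25, 100.0, 3000.0, 25000.0],
            "center": 2017.0,
            "year_min": 2009,
            "year_max": 2025,
        },
    }


@dataclass
class CorpusConfig:
    """Generator configuration; every mix must sum to 1."""

    n_gsm: int = 200
    seed: int = 0
    technology_mix: dict = dc_field(default_factory=_default_technology_mix)
    p_empty_characteristics: float = 0.10
    p_structured: float = 0.60
    adversarial_rate: float = 0.25  # share of almost-structured not_structured GSMs
    tag_word_count_distribution: dict = dc_field(default_factory=lambda: {1: 1.0})
    value_word_count_distribution: dict = dc_field(
        default_factory=lambda: {1: 0.7, 2: 0.2, 3: 0.1}
    )
    n_random_pairs: int = 0  # extra pairs with sampled tag/value word counts
    tag_vocabulary: dict = dc_field(default_factory=_default_tag_vocabulary)
    strain_alias_list: list = dc_field(
        default_factory=lambda: ["strain", "strain background"]
    )
    p_two_channel: float = 0.2  # microarray only
    manufacturer_mix: list = dc_field(default_factory=_default_manufacturer_mix)
    supplementary_file_mix: dict = dc_field(default_factory=_default_supplementary_mix)
    organism_mix: dict = dc_field(default_factory=_default_organism_mix)
    # word-count ceilings observed per technology (longest tags: 86 / 12 words)
    max_words: dict = dc_field(
        default_factory=lambda: {"microarray": 86, "rnaseq": 12}
    )
    growth: dict = dc_field(default_factory=_default_growth)

    def __post_init__(self):
        self.validate()

    def validate(self):
        if self.n_gsm < 0:
            raise ConfigError("n_gsm must be >= 0")
        for name, mix in (
            ("technology_mix", self.technology_mix),
            ("supplementary_file_mix", self.supplementary_file_mix),
            ("organism_mix", self.organism_mix),
            ("tag_word_count_distribution", self.tag_word_count_distribution),
            ("value_word_count_distribution", self.value_word_count_distribution),
        ):
            total = sum(mix.values())
            if abs(total - 1.0) > 1e-9:
                raise ConfigError(f"{name} sums to {total}, expected 1")
            if any(p < 0 for p in mix.values()):
                raise ConfigError(f"{name} has negative probability")
        total = sum(e["prob"] for e in self.manufacturer_mix)
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"manufacturer_mix sums to {total}, expected 1")
        for p, name in (
            (self.p_empty_characteristics, "p_empty_characteristics"),
            (self.p_structured, "p_structured"),
            (self.adversarial_rate, "adversarial_rate"),
            (self.p_two_channel, "p_two_channel"),
        ):
            if not 0.0 <= p <= 1.0:
                raise ConfigError(f"{name}={p} outside [0, 1]")
        if self.p_empty_characteristics + self.p_structured > 1.0 + 1e-9:
            raise ConfigError("p_empty + p_structured exceeds 1")
        if self.p_structured > 0 and not self.tag_vocabulary and not self.n_random_pairs:
            raise ConfigError(
                "structured GSMs requested but no tag vocabulary or random pairs"
            )

    def to_dict(self) -> dict:
        from dataclasses import asdict

        d = asdict(self)
        # JSON object keys are strings; keep word-count supports explicit
        d["tag_word_count_distribution"] = {
            str(k): v for k, v in self.tag_word_count_distribution.items()
        }
        d["value_word_count_distribution"] = {
            str(k): v for k, v in self.value_word_count_distribution.items()
        }
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CorpusConfig":
        d = dict(d)
        for key in ("tag_word_count_distribution", "value_word_count_distribution"):
            if key in d:
                d[key] = {int(k): v for k, v in d[key].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# sampling helpers
# ---------------------------------------------------------------------------


def _rng(seed: int, index: int, aspect: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence(entropy=seed, spawn_key=(index, aspect))
    )


def _categorical(rng: np.random.Generator, mix: dict):
    keys = list(mix)
    probs = np.array([mix[k] for k in keys], dtype=float)
    probs = probs / probs.sum()
    return keys[int(rng.choice(len(keys), p=probs))]


def _sample_words(rng: np.random.Generator, n: int) -> str:
    return " ".join(rng.choice(_WORDS) for _ in range(n))


def _growth_year_weights(spec: dict) -> tuple:
    """Per-year weights proportional to the configured cumulative curve's
    yearly increments."""
    years = np.arange(spec["year_min"], spec["year_max"] + 1)
    if spec["model"] == "logistic":
        L, k, x0 = spec["L"], spec["k"], spec["x0"]
        cum = L / (1.0 + np.exp(-k * (years - x0)))
        prev = L / (1.0 + np.exp(-k * (years - 1 - x0)))
    elif spec["model"] == "cubic":
        a3, a2, a1, a0 = spec["coeffs_centered"]
        c = spec["center"]

        def cubic(x):
            t = x - c
            return ((a3 * t + a2) * t + a1) * t + a0

        cum = cubic(years.astype(float))
        prev = cubic(years.astype(float) - 1)
    else:
        raise ConfigError(f"unknown growth model {spec['model']!r}")
    inc = np.clip(cum - prev, 0.0, None)
    if inc.sum() <= 0:
        raise ConfigError("growth curve yields no positive yearly increments")
    return years, inc / inc.sum()


# ---------------------------------------------------------------------------
# per-GSM generation
# ---------------------------------------------------------------------------


def _gen_characteristics(config: CorpusConfig, i: int) -> dict:
    """Sample characteristics content and the intended structure profile."""
    rng = _rng(config.seed, i, _ASPECT_CHAR)
    u = rng.random()
    if u < config.p_empty_characteristics:
        return {"char_label": "empty", "pairs": [], "lines": [],
                "max_tag_words": 0, "max_value_words": 0}
    if u < config.p_empty_characteristics + config.p_structured:
        pairs = []
        for tag, p_inc in config.tag_vocabulary.items():
            if rng.random() < p_inc:
                n_words = int(_categorical(rng, config.value_word_count_distribution))
                pairs.append((tag, _sample_words(rng, n_words)))
        for _ in range(config.n_random_pairs):
            nt = int(_categorical(rng, config.tag_word_count_distribution))
            nv = int(_categorical(rng, config.value_word_count_distribution))
            pairs.append((_sample_words(rng, nt), _sample_words(rng, nv)))
        if not pairs:  # force at least one pair so the GSM is not empty
            tag = next(iter(config.tag_vocabulary), None)
            if tag is None:
                nt = int(_categorical(rng, config.tag_word_count_distribution))
                tag = _sample_words(rng, nt)
            nv = int(_categorical(rng, config.value_word_count_distribution))
            pairs.append((tag, _sample_words(rng, nv)))
        lines = [f"{tag}: {value}" for tag, value in pairs]
        return {
            "char_label": "structured",
            "pairs": pairs,
            "lines": lines,
            "max_tag_words": max(len(t.split()) for t, _ in pairs),
            "max_value_words": max(len(v.split()) for _, v in pairs),
        }
    # not structured: colon-free prose, or an adversarial almost-structured case
    if rng.random() < config.adversarial_rate:
        variant = ["empty_tag", "empty_value", "mixed"][int(rng.integers(3))]
        if variant == "empty_tag":
            lines = [f": {_sample_words(rng, 2)}"]
        elif variant == "empty_value":
            lines = [f"{_sample_words(rng, 1)}:"]
        else:  # one conforming pair plus one broken line
            lines = [f"strain: {_sample_words(rng, 1)}", _sample_words(rng, 4)]
    else:
        lines = [_sample_words(rng, int(rng.integers(3, 9)))]
    return {"char_label": "not_structured", "pairs": [], "lines": lines,
            "max_tag_words": 0, "max_value_words": 0}


def manifest_structure_label(entry: dict, k_tag: float, k_value: float) -> str:
    """Predict the audit's structure label for one manifest GSM entry."""
    if entry["char_label"] == "empty":
        return "empty"
    if entry["char_label"] == "not_structured":
        return "not_structured"
    if entry["max_tag_words"] <= k_tag and entry["max_value_words"] <= k_value:
        return "putative_structured"
    return "not_structured"


def expected_structure_counts(manifest: dict, k: float) -> dict:
    """Expected (n_empty, n_structured, n_not_structured) at joint limit k."""
    counts = {"empty": 0, "putative_structured": 0, "not_structured": 0}
    for g in manifest["gsms"]:
        counts[manifest_structure_label(g, k, k)] += 1
    return {
        "n_empty": counts["empty"],
        "n_structured": counts["putative_structured"],
        "n_not_structured": counts["not_structured"],
    }


_SUPP_KIND_FILES = {
    "none": (),
    "cel": ("{acc}.CEL.gz",),
    "txt": ("{acc}.txt.gz",),
    "pair": ("{acc}_532.pair.gz",),
    "xys": ("{acc}.xys.gz",),
    "image": ("{acc}_scan.jpg",),
    "spreadsheet": ("{acc}_summary.xlsx",),
    "mixed": ("{acc}.txt.gz", "{acc}_scan.jpg"),
}

_SUPP_KIND_EXTS = {
    "none": (),
    "cel": ("cel",),
    "txt": ("txt",),
    "pair": ("pair",),
    "xys": ("xys",),
    "image": ("jpg",),
    "spreadsheet": ("xlsx",),
    "mixed": ("txt", "jpg"),
}

_NONPROCESSABLE = {"tiff", "tif", "jpg", "jpeg", "xls", "xlsx"}

_MANUF_MATCH = {
    "Affymetrix": {"cel"},
    "Agilent": {"txt"},
    "NimbleGen": {"xys", "pair"},
}


def _expected_triage(kind: str, gpl_entry: dict) -> tuple:
    """Generator-side mirror of the triage rules (the manifest oracle)."""
    exts = _SUPP_KIND_EXTS[kind]
    if not exts:
        return "unrecoverable", "no_supplementary_files"
    if gpl_entry["canonical"] == "none":
        return "unrecoverable", "no_manufacturer"
    if all(e in _NONPROCESSABLE for e in exts):
        return "unrecoverable", "all_files_nonprocessable"
    if gpl_entry["distribution"] == "noncommercial":
        return "unrecoverable", "noncommercial_distribution"
    if gpl_entry["distribution"] in ("commercial", "custom_commercial"):
        match = _MANUF_MATCH.get(gpl_entry["canonical"], set())
        if match & set(exts):
            return "reusable", f"manufacturer_extension_match:{gpl_entry['canonical']}"
    return "potentially_reusable", "default"


def _expected_taxon(organism_key: str, organisms: list, lineage) -> str:
    if organism_key == "__multiple__":
        return "multiple_organism"
    if organism_key == "__synthetic__":
        return "synthetic_chimeric"
    if organism_key == "__environmental__":
        return "environmental_samples"
    lin = lineage.lookup(organisms[0])
    return lin.superkingdom if lin is not None else "unclassified"


# ---------------------------------------------------------------------------
# corpus assembly
# ---------------------------------------------------------------------------


def generate_corpus(config: CorpusConfig) -> tuple:
    """Generate one SOFT family document plus its ground-truth manifest.

    Deterministic given ``config.seed``; the emitted text parses cleanly with
    :func:`geoaudit.soft_io.parse_soft` and the manifest predicts every audit
    output exactly in noiseless settings.

    Returns ``(soft_text, manifest_dict)``.
    """
    config.validate()
    lineage = load_lineage()
    doc = SoftDocument()

    # platforms: one per manufacturer-mix entry plus a sequencing platform
    gpl_entries = []
    for j, entry in enumerate(config.manufacturer_mix):
        acc = f"GPL{j + 1:04d}"
        gpl_entries.append({**entry, "accession": acc})
        ent = SoftEntity("PLATFORM", acc)
        ent.items.append(SoftAttribute("Platform_title", f"Synthetic array design {j + 1}"))
        ent.items.append(
            SoftAttribute("Platform_technology", "in situ oligonucleotide")
        )
        if entry["raw"]:
            ent.items.append(SoftAttribute("Platform_manufacturer", entry["raw"]))
        if entry["distribution"] != "unknown":
            dist = entry["distribution"].replace("_", "-")
            ent.items.append(SoftAttribute("Platform_distribution", dist))
        doc.entities.append(ent)
    rnaseq_gpl = f"GPL{len(config.manufacturer_mix) + 1:04d}"
    ent = SoftEntity("PLATFORM", rnaseq_gpl)
    ent.items.append(SoftAttribute("Platform_title", "Synthetic sequencing platform"))
    ent.items.append(
        SoftAttribute("Platform_technology", "high-throughput sequencing")
    )
    doc.entities.append(ent)

    series_acc = "GSE0001"
    series_ent = SoftEntity("SERIES", series_acc)
    series_ent.items.append(SoftAttribute("Series_title", "Synthetic audit corpus"))
    doc.entities.append(series_ent)

    year_weights = {
        tech: _growth_year_weights(spec) for tech, spec in config.growth.items()
    }
    p_micro = config.technology_mix.get("microarray", 0.0)

    gsm_manifest = []
    for i in range(config.n_gsm):
        acc = f"GSM{i + 1:06d}"
        tech = (
            "microarray"
            if _rng(config.seed, i, _ASPECT_TECH).random() < p_micro
            else "rnaseq"
        )
        years, weights = year_weights[tech]
        yrng = _rng(config.seed, i, _ASPECT_YEAR)
        year = int(years[int(yrng.choice(len(years), p=weights))])
        drng = _rng(config.seed, i, _ASPECT_DATE)
        month = int(drng.integers(1, 13))
        day = int(drng.integers(1, 29))
        date_str = f"{_MONTH_ABBREV[month - 1]} {day:02d} {year}"

        char = _gen_characteristics(config, i)

        orng = _rng(config.seed, i, _ASPECT_ORG)
        organism_key = _categorical(orng, config.organism_mix)
        if organism_key == "__multiple__":
            names = [n for n in config.organism_mix if not n.startswith("__")]
            picks = orng.choice(len(names), size=2, replace=False)
            organisms = [names[int(p)] for p in picks]
        elif organism_key in _SPECIAL_ORGANISMS:
            organisms = [_SPECIAL_ORGANISMS[organism_key]]
        else:
            organisms = [organism_key]

        n_channels = 1
        if tech == "microarray":
            crng = _rng(config.seed, i, _ASPECT_CHANNEL)
            if crng.random() < config.p_two_channel:
                n_channels = 2
            grng = _rng(config.seed, i, _ASPECT_GPL)
            probs = np.array([e["prob"] for e in gpl_entries])
            gpl_entry = gpl_entries[int(grng.choice(len(gpl_entries), p=probs / probs.sum()))]
            srng = _rng(config.seed, i, _ASPECT_SUPP)
            supp_kind = _categorical(srng, config.supplementary_file_mix)
            supp_files = [t.format(acc=acc) for t in _SUPP_KIND_FILES[supp_kind]]
            triage_label, triage_rule = _expected_triage(supp_kind, gpl_entry)
        else:
            gpl_entry = None
            supp_kind = "fastq"
            supp_files = [f"{acc}.fastq.gz"]
            triage_label = triage_rule = None

        entity = SoftEntity("SAMPLE", acc)
        add = entity.items.append
        add(SoftAttribute("Sample_title", f"synthetic sample {i + 1}"))
        add(SoftAttribute("Sample_geo_accession", acc))
        add(SoftAttribute("Sample_status", f"Public on {date_str}"))
        add(SoftAttribute("Sample_submission_date", date_str))
        add(SoftAttribute("Sample_channel_count", str(n_channels)))
        for ch in range(1, n_channels + 1):
            add(SoftAttribute(f"Sample_organism_ch{ch}", organisms[0]))
            if len(organisms) > 1:
                add(SoftAttribute(f"Sample_organism_ch{ch}", organisms[1]))
        for line in char["lines"]:
            add(SoftAttribute("Sample_characteristics_ch1", line))
        add(SoftAttribute("Sample_molecule_ch1", "total RNA"))
        if tech == "microarray":
            add(SoftAttribute("Sample_label_ch1", "Cy3"))
            if n_channels == 2:
                add(SoftAttribute("Sample_label_ch2", "Cy5"))
            add(SoftAttribute("Sample_hyb_protocol", "standard hybridization"))
            add(SoftAttribute("Sample_platform_id", gpl_entry["accession"]))
        else:
            add(SoftAttribute("Sample_library_strategy", "RNA-Seq"))
            add(SoftAttribute("Sample_library_source", "transcriptomic"))
            add(SoftAttribute("Sample_library_selection", "cDNA"))
            add(SoftAttribute("Sample_instrument_model", "Illumina NovaSeq 6000"))
            add(SoftAttribute("Sample_platform_id", rnaseq_gpl))
        add(SoftAttribute("Sample_series_id", series_acc))
        if supp_files:
            for f in supp_files:
                add(SoftAttribute("Sample_supplementary_file", f))
        else:
            add(SoftAttribute("Sample_supplementary_file", "NONE"))
        add(SoftAttribute("Sample_type", "RNA"))
        doc.entities.append(entity)

        gsm_manifest.append(
            {
                "accession": acc,
                "technology": tech,
                "year": year,
                "char_label": char["char_label"],
                "pairs": [list(p) for p in char["pairs"]],
                "max_tag_words": char["max_tag_words"],
                "max_value_words": char["max_value_words"],
                "n_channels": n_channels,
                "organism_key": organism_key,
                "organisms": organisms,
                "taxon_label": _expected_taxon(organism_key, organisms, lineage),
                "supp_kind": supp_kind,
                "supplementary_files": supp_files,
                "platform": gpl_entry["accession"] if gpl_entry else rnaseq_gpl,
                "manufacturer_raw": gpl_entry["raw"] if gpl_entry else None,
                "manufacturer_canonical": gpl_entry["canonical"] if gpl_entry else None,
                "distribution": gpl_entry["distribution"] if gpl_entry else None,
                "triage_label": triage_label,
                "triage_rule": triage_rule,
            }
        )

    manifest = {
        "config": config.to_dict(),
        "gsms": gsm_manifest,
        "expected": _corpus_expectations(gsm_manifest),
    }
    return write_soft(doc), manifest


def _corpus_expectations(gsm_manifest: list) -> dict:
    cumulative: dict = {}
    for tech in ("microarray", "rnaseq"):
        years = sorted(g["year"] for g in gsm_manifest if g["technology"] == tech)
        if not years:
            continue
        series: dict = {}
        total = 0
        counts: dict = {}
        for y in years:
            counts[y] = counts.get(y, 0) + 1
        for y in range(min(years), max(years) + 1):
            total += counts.get(y, 0)
            series[str(y)] = total
        cumulative[tech] = series
    triage_counts: dict = {}
    taxon_counts: dict = {}
    for g in gsm_manifest:
        if g["triage_label"] is not None:
            triage_counts[g["triage_label"]] = triage_counts.get(g["triage_label"], 0) + 1
        key = (g["taxon_label"], g["technology"])
        taxon_counts["|".join(key)] = taxon_counts.get("|".join(key), 0) + 1
    structure_by_k = {
        str(k): None for k in list(range(1, 11)) + ["inf"]
    }
    for k_key in list(structure_by_k):
        k = float("inf") if k_key == "inf" else int(k_key)
        structure_by_k[k_key] = expected_structure_counts({"gsms": gsm_manifest}, k)
    return {
        "cumulative_by_year": cumulative,
        "triage_counts": triage_counts,
        "taxon_counts": taxon_counts,
        "structure_counts_by_k": structure_by_k,
    }


def write_corpus(config: CorpusConfig, out_dir) -> dict:
    """Write ``corpus.soft`` and ``manifest.json`` under *out_dir*."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    soft_text, manifest = generate_corpus(config)
    soft_path = out_dir / "corpus.soft"
    manifest_path = out_dir / "manifest.json"
    soft_path.write_text(soft_text, encoding="utf-8")
    manifest_path.write_text(
        json.dumps(manifest, indent=1, sort_keys=True) + "\n", encoding="utf-8"
    )
    return {"soft": soft_path, "manifest": manifest_path}


def generate_reference_fixture(out_dir) -> dict:
    """Write the versioned reference fixtures (field catalog, manufacturer
    aliases, lineage) to *out_dir*; contents are byte-stable across runs."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in ("field_catalog.tsv", "manufacturer_aliases.tsv", "lineage.tsv"):
        src = Path(resources.files("geoaudit") / "data" / name)
        dst = out_dir / name
        copyfile(src, dst)
        out[name] = dst
    return out
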