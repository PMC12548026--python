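# geoaudit

An audit pipeline for transcriptomic metadata in GEO's SOFT family-file
format. It quantifies how structured and complete sample metadata actually
is, triages microarray raw-data reusability, and models submission growth —
all testable offline against a bundled reference field catalog and a
synthetic SOFT corpus generator with an exact ground-truth manifest.

## What it does

- **`geoaudit.soft_io`** — lossless parser/writer for the SOFT dialect
  (`^` entity lines, `!` attributes split at the first `=`, `#` column
  descriptions, table delimiters), plus YAML export and extraction of
  flattened GSM/GPL records.
- **`geoaudit.field_catalog`** — field inventory, channel-suffix redundancy
  reduction (`characteristics_ch1` → `characteristics`), and classification
  against the bundled reference catalog (45 canonical dataset fields, of
  which 32 are GEO-documented and 13 reported only in the bacterial
  dataset; SAGE-only and table-delimiter attributes tracked separately).
- **`geoaudit.characteristics`** — `<tag>: <value>` parsing, per-GSM
  structuredness classification (`empty` / `putative_structured` /
  `not_structured`) under a word-count stringency `k`, stringency sweeps,
  the GSM × tag table with missing-value profiles, tag frequency ranking,
  and strain-like tag detection.
- **`geoaudit.triage`** — reusability triage of microarray GSMs
  (`reusable` / `potentially_reusable` / `unrecoverable`) from
  supplementary-file types, normalized manufacturer names, and platform
  distribution class, with the fired rule recorded for every decision.
- **`geoaudit.taxonomy`** — taxonomic labelling (superkingdom / phylum /
  species, plus multiple-organism and synthetic/environmental categories)
  from a pluggable lineage TSV.
- **`geoaudit.growth`** — cumulative yearly submission series, logistic and
  (centered) cubic least-squares fits, inflection/asymptote analysis, and
  fold-change projections.
- **`geoaudit.synthetic`** — deterministic corpus generator with per-GSM,
  per-aspect random substreams and a manifest that predicts every audit
  output exactly.

## CLI

```bash
# generate a synthetic corpus + ground-truth manifest
geoaudit gen-corpus --n 500 --seed 42 --out scratch/corpus

# run the full audit and write report.json + stage TSVs
geoaudit report --input scratch/corpus/corpus.soft --out scratch/report \
    --k-max 10 --k-tag inf --k-value inf

# individual stages
geoaudit audit-metadata       --input ... --out ...
geoaudit audit-characteristics --input ... --out ...
geoaudit triage-arrays        --input ... --out ...
geoaudit profile-taxa         --input ... --out ... --rank phylum
geoaudit fit-growth           --input ... --out ...
```

Reports are deterministic (version + config hash, no timestamps): re-running
on the same inputs yields byte-identical JSON.

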