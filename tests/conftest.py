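"""Shared fixtures: tiny hand-written SOFT documents and generated corpora."""

from __future__ import annotations

import pytest

from geoaudit.soft_io import GsmRecord, parse_soft
from geoaudit.synthetic import CorpusConfig, generate_corpus

SMALL_SOFT = """\
^PLATFORM = GPL99
!Platform_title = Test array
!Platform_manufacturer = Affymetrix, Inc.
!Platform_distribution = commercial
!Platform_technology = in situ oligonucleotide
^SAMPLE = GSM1
!Sample_title = sample one
!Sample_channel_count = 1
!Sample_submission_date = Mar 05 2010
!Sample_organism_ch1 = Escherichia coli
!Sample_characteristics_ch1 = strain: MG1655
!Sample_characteristics_ch1 = medium: LB
!Sample_label_ch1 = Cy3
!Sample_platform_id = GPL99
!Sample_supplementary_file = GSM1.CEL.gz
^SAMPLE = GSM2
!Sample_title = sample two
!Sample_channel_count = 2
!Sample_submission_date = Jul 20 2012
!Sample_organism_ch1 = Bacillus subtilis
!Sample_organism_ch2 = Bacillus subtilis
!Sample_characteristics_ch1 = grown overnight in LB
!Sample_characteristics_ch2 = strain: 168
!Sample_label_ch1 = Cy3
!Sample_label_ch2 = Cy5
!Sample_platform_id = GPL99
!Sample_supplementary_file = NONE
"""


def make_gsm(accession="GSM1", characteristics=(), **kwargs) -> GsmRecord:
    """Build a GsmRecord with characteristics lines on channel 1."""
    rec = GsmRecord(accession=accession, **kwargs)
    rec.characteristics = {1: list(characteristics)} if characteristics else {}
    if rec.characteristics and not rec.channel_count:
        rec.channel_count = 1
    return rec


@pytest.fixture
def small_doc():
    return parse_soft(SMALL_SOFT)


@pytest.fixture(scope="session")
def default_corpus():
    """A mid-sized corpus with the default configuration (seed-fixed)."""
    config = CorpusConfig(n_gsm=500, seed=42)
    text, manifest = generate_corpus(config)
    return config, text, manifest
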