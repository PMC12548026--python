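"""Characteristics parsing, per-GSM classification, sweep, table, tags."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from geoaudit.characteristics import (
    EMPTY,
    NOT_STRUCTURED,
    PUTATIVE_STRUCTURED,
    UNBOUNDED,
    build_table,
    canonical_tag,
    classify_gsm,
    parse_characteristics,
    strain_like_tags,
    stringency_sweep,
    tag_frequency,
)

from conftest import make_gsm


def oracle_split(raw):
    """Brute-force split oracle: scan all colon positions, prefer the
    earliest colon+space split, else the earliest bare colon."""
    candidates_space = [i for i, c in enumerate(raw) if raw[i : i + 2] == ": "]
    candidates_bare = [i for i, c in enumerate(raw) if c == ":"]
    for pool in (candidates_space, candidates_bare):
        if pool:
            i = min(pool)
            return raw[:i].strip(), raw[i + 1 :].strip()
    return None, None


class TestParsePair:
    def test_simple_pair(self):
        p = parse_characteristics("strain: MG1655")
        assert (p.tag, p.value) == ("strain", "MG1655")
        assert (p.tag_words, p.value_words) == (1, 1)
        assert p.parsed

    def test_no_colon(self):
        p = parse_characteristics("grown overnight in LB")
        assert not p.parsed
        assert p.tag is None and p.value is None
        assert (p.tag_words, p.value_words) == (0, 0)

    def test_url_value_not_split_inside(self):
        p = parse_characteristics("source: http://x.org/a")
        assert (p.tag, p.value) == ("source", "http://x.org/a")

    @given(
        st.text(
            alphabet=st.characters(blacklist_categories=["Cs"], blacklist_characters="\n"),
            max_size=60,
        )
    )
    def test_matches_bruteforce_oracle(self, raw):
        p = parse_characteristics(raw)
        tag, value = oracle_split(raw)
        if tag and value:
            assert p.parsed and (p.tag, p.value) == (tag, value)
        else:
            assert not p.parsed

    def test_bare_colon_fallback(self):
        p = parse_characteristics("strain:MG1655")
        assert (p.tag, p.value) == ("strain", "MG1655")

    def test_empty_tag_unparsed(self):
        assert not parse_characteristics(": value").parsed

    def test_empty_value_unparsed(self):
        assert not parse_characteristics("tag:").parsed

    def test_multiword_counts(self):
        p = parse_characteristics("growth phase: late exponential phase")
        assert (p.tag_words, p.value_words) == (2, 3)


class TestClassify:
    def test_no_characteristics_is_empty(self):
        assert classify_gsm(make_gsm()).label == EMPTY

    def test_whitespace_only_is_empty(self):
        g = make_gsm(characteristics=["   ", "\t"])
        assert classify_gsm(g).label == EMPTY

    def test_all_conforming_pairs_structured(self):
        g = make_gsm(characteristics=["strain: MG1655", "medium: LB"])
        assert classify_gsm(g, 1, 1).label == PUTATIVE_STRUCTURED

    def test_one_bad_pair_spoils_the_gsm(self):
        g = make_gsm(characteristics=["strain: MG1655", "no colon here"])
        assert classify_gsm(g, UNBOUNDED, UNBOUNDED).label == NOT_STRUCTURED

    def test_word_limit_enforced(self):
        g = make_gsm(characteristics=["growth phase: late exponential"])
        assert classify_gsm(g, 1, 1).label == NOT_STRUCTURED
        assert classify_gsm(g, 2, 2).label == PUTATIVE_STRUCTURED

    def test_independent_limits(self):
        g = make_gsm(characteristics=["growth phase: LB"])
        assert classify_gsm(g, 2, 1).label == PUTATIVE_STRUCTURED
        assert classify_gsm(g, 1, 2).label == NOT_STRUCTURED

    def test_bad_limit_rejected(self):
        with pytest.raises(ValueError):
            classify_gsm(make_gsm(), 0, 1)

    def test_channels_pooled(self):
        g = make_gsm()
        g.characteristics = {1: ["strain: x"], 2: ["bad line"]}
        assert classify_gsm(g).label == NOT_STRUCTURED


class TestSweep:
    def make_corpus(self):
        return [
            make_gsm("GSM1", ["strain: MG1655"]),
            make_gsm("GSM2", ["growth phase: late exponential phase"]),
            make_gsm("GSM3", ["no colon"]),
            make_gsm("GSM4"),
        ]

    def test_counts_partition_at_every_k(self):
        sweep = stringency_sweep(self.make_corpus(), 5)
        totals = sweep[["n_empty", "n_structured", "n_not_structured"]].sum(axis=1)
        assert (totals == 4).all()

    def test_empty_constant_structured_monotone(self):
        sweep = stringency_sweep(self.make_corpus(), 5)
        assert sweep["n_empty"].nunique() == 1
        assert (np.diff(sweep["n_structured"]) >= 0).all()
        assert (np.diff(sweep["n_not_structured"]) <= 0).all()

    def test_all_one_word_corpus_constant(self):
        gsms = [make_gsm(f"G{i}", ["strain: x"]) for i in range(3)]
        sweep = stringency_sweep(gsms, 4)
        assert sweep["n_structured"].nunique() == 1

    def test_exact_thresholds(self):
        sweep = stringency_sweep(self.make_corpus(), 5).set_index("k")
        assert sweep.loc[1.0, "n_structured"] == 1  # only the 1:1 GSM
        assert sweep.loc[3.0, "n_structured"] == 2  # 2-word tag, 3-word value
        assert sweep.loc[UNBOUNDED, "n_structured"] == 2

    def test_matches_generator_manifest(self, default_corpus):
        from geoaudit.soft_io import extract_gsms, parse_soft
        from geoaudit.synthetic import expected_structure_counts

        _, text, manifest = default_corpus
        gsms = extract_gsms(parse_soft(text))
        sweep = stringency_sweep(gsms, 5)
        for _, row in sweep.iterrows():
            expected = expected_structure_counts(manifest, row["k"])
            assert row["n_empty"] == expected["n_empty"]
            assert row["n_structured"] == expected["n_structured"]
            assert row["n_not_structured"] == expected["n_not_structured"]


class TestTable:
    def test_union_semantics_and_missing_fraction(self):
        g1 = make_gsm("GSM1", ["strain: A", "medium: LB"])
        g2 = make_gsm("GSM2", ["strain: B"])
        table = build_table([g1, g2], 1, 1)
        assert set(table.frame.columns) == {"strain", "medium"}
        assert table.column_missing_fraction["medium"] == 0.5
        assert table.column_missing_fraction["strain"] == 0.0

    def test_identical_tag_sets_no_missing(self):
        gsms = [make_gsm(f"G{i}", ["strain: x", "medium: LB"]) for i in range(4)]
        table = build_table(gsms, 1, 1)
        assert (table.column_missing_fraction == 0).all()

    def test_non_structured_input_rejected(self):
        with pytest.raises(ValueError):
            build_table([make_gsm("G1", ["no colon"])])

    def test_duplicate_tag_keeps_first(self):
        g = make_gsm("G1", ["strain: first", "strain: second"])
        table = build_table([g])
        assert table.frame.loc["G1", "strain"] == "first"
        assert table.collisions == 1

    def test_tag_canonicalization_folds_case_and_whitespace(self):
        g1 = make_gsm("G1", ["Strain: A"])
        g2 = make_gsm("G2", ["strain : B"])
        table = build_table([g1, g2])
        assert list(table.frame.columns) == ["strain"]
        # values are never canonicalized
        assert set(table.frame["strain"]) == {"A", "B"}

    def test_cell_conservation(self):
        gsms = [
            make_gsm("G1", ["strain: A", "medium: LB"]),
            make_gsm("G2", ["strain: B"]),
            make_gsm("G3", ["strain: C", "strain: dup", "phase: log"]),
        ]
        table = build_table(gsms)
        n_pairs = 2 + 1 + 3
        assert table.n_nonmissing_cells == n_pairs - table.collisions

    def test_missing_fraction_matches_binomial_simulation(self):
        # per-tag inclusion probability p -> mean missing fraction ~= 1 - p
        rng = np.random.default_rng(123)
        p = 0.7
        n = 2000
        gsms = []
        for i in range(n):
            lines = ["anchor: x"]  # guarantees structured, always present
            if rng.random() < p:
                lines.append("strain: A")
            gsms.append(make_gsm(f"G{i}", lines))
        table = build_table(gsms, 1, 1)
        missing = table.column_missing_fraction["strain"]
        tol = 4 * np.sqrt(p * (1 - p) / n)
        assert abs(missing - (1 - p)) < tol


class TestTagStats:
    def test_single_gsm_single_tag(self):
        table = build_table([make_gsm("G1", ["strain: x"])])
        assert tag_frequency(table) == [("strain", 100.0)]

    def test_top_tag_matches_min_missing(self):
        gsms = [
            make_gsm("G1", ["strain: A", "medium: LB"]),
            make_gsm("G2", ["strain: B"]),
        ]
        table = build_table(gsms)
        top_tag, top_pct = tag_frequency(table)[0]
        expected = ((1 - table.column_missing_fraction) * 100).max()
        assert top_pct == expected

    def test_matches_bruteforce_recount(self, default_corpus):
        from geoaudit.characteristics import PUTATIVE_STRUCTURED
        from geoaudit.soft_io import extract_gsms, parse_soft

        _, text, _ = default_corpus
        gsms = [
            g
            for g in extract_gsms(parse_soft(text))
            if classify_gsm(g).label == PUTATIVE_STRUCTURED
        ]
        table = build_table(gsms)
        ranked = tag_frequency(table)
        # independent recount straight from the raw pairs
        counts = {}
        for g in gsms:
            seen = set()
            for raw in g.all_characteristics():
                pair = parse_characteristics(raw)
                tag = canonical_tag(pair.tag)
                if tag not in seen:
                    seen.add(tag)
                    counts[tag] = counts.get(tag, 0) + 1
        expected = sorted(
            ((t, c / len(gsms) * 100) for t, c in counts.items()),
            key=lambda kv: (-kv[1], kv[0]),
        )
        assert [t for t, _ in ranked] == [t for t, _ in expected]
        np.testing.assert_allclose(
            [p for _, p in ranked], [p for _, p in expected], rtol=1e-12
        )

    def test_empty_table_empty_ranking(self):
        import pandas as pd

        from geoaudit.characteristics import CharacteristicsTable

        assert tag_frequency(CharacteristicsTable(pd.DataFrame())) == []

    def test_strain_like_rule(self):
        subset, prop = strain_like_tags({"strain", "Strain name", "medium"})
        assert subset == {"strain", "Strain name"}
        assert prop == pytest.approx(2 / 3)

    def test_word_boundary_excludes_constraint(self):
        subset, prop = strain_like_tags({"constraint"})
        assert subset == set()
        assert prop == 0.0

    def test_punctuation_stripped(self):
        subset, _ = strain_like_tags({"strain/isolate", "(strain)"})
        assert subset == {"strain/isolate", "(strain)"}

    def test_recovers_generator_alias_list(self, default_corpus):
        from geoaudit.soft_io import extract_gsms, parse_soft

        config, text, _ = default_corpus
        gsms = [
            g
            for g in extract_gsms(parse_soft(text))
            if classify_gsm(g).label == PUTATIVE_STRUCTURED
        ]
        table = build_table(gsms)
        subset, _ = strain_like_tags(table.frame.columns)
        present_aliases = {
            a for a in config.strain_alias_list if a in set(table.frame.columns)
        }
        assert subset == present_aliases
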