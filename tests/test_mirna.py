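"""miRNA grammar, canonicalisation, catalog validation and the annual matrix."""

from __future__ import annotations

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from bibliomir import (
    BibRecord,
    Corpus,
    annual_mirna_matrix,
    bundled_catalog,
    canonicalize_token,
    extract_mirna_tokens,
    load_catalog,
    rank_mirnas,
    validate_mention,
)
from bibliomir.mirna import extract_record_mentions


@pytest.fixture(scope="module")
def catalog():
    return bundled_catalog()


class TestExtraction:
    def test_landmark_title_yields_both_renderings(self):
        text = (
            "MicroRNA-21 (miR-21) post-transcriptionally downregulates tumor "
            "suppressor Pdcd4 and stimulates invasion, intravasation and "
            "metastasis in colorectal cancer"
        )
        assert [t.text for t in extract_mirna_tokens(text)] == ["MicroRNA-21", "miR-21"]

    def test_empty_text(self):
        assert extract_mirna_tokens("") == []

    @pytest.mark.parametrize(
        "text,expected",
        [
            ("hsa-miR-195-5p and miR-19b-1-5p", ["hsa-miR-195-5p", "miR-19b-1-5p"]),
            ("anti-miR-21 therapy", ["miR-21"]),
            ("let-7a-5p targets RAS", ["let-7a-5p"]),
            ("the MIR155HG host gene", []),  # gene symbol, not an identifier
            ("miRNAs regulate mRNAs", []),  # stem without a number
            ("microRNA 21 and MIR-34A", ["microRNA 21", "MIR-34A"]),
        ],
    )
    def test_grammar_boundaries(self, text, expected):
        assert [t.text for t in extract_mirna_tokens(text)] == expected

    def test_spans_non_overlapping_and_recall_on_planted_text(self, synthetic_corpus, ground_truth):
        """Every planted token is recovered; spans never overlap."""
        catalog = bundled_catalog()
        for rec in synthetic_corpus.records[:300]:
            for text in (rec.title, rec.abstract):
                spans = extract_mirna_tokens(text)
                for a, b in zip(spans, spans[1:]):
                    assert a.end <= b.start
            mentions = extract_record_mentions(rec, catalog)
            recovered = {m.canonical_id for m in mentions if m.valid}
            assert recovered == ground_truth.mirna_mentions[rec.record_id]


class TestCanonicalize:
    @pytest.mark.parametrize(
        "raw,expected",
        [
            ("hsa-miR-195-5p", "miR-195-5p"),
            ("microRNA 21", "miR-21"),
            ("MIR-34A", "miR-34a"),
            ("mir-19b-1", "miR-19b-1"),
            ("hsa-let-7a", "let-7a"),
            ("LET-7A-5P", "let-7a-5p"),
            ("miRNA-133b", "miR-133b"),
        ],
    )
    def test_folding(self, raw, expected):
        assert canonicalize_token(raw) == expected

    def test_non_grammar_input_is_programmer_error(self):
        with pytest.raises(ValueError):
            canonicalize_token("PTEN")

    @given(
        num=st.integers(1, 9999),
        letter=st.sampled_from(["", "a", "b", "c"]),
        arm=st.sampled_from(["", "-5p", "-3p"]),
        stem=st.sampled_from(["miR-", "mir-", "MIR-", "microRNA-", "miRNA ", "hsa-miR-"]),
    )
    @settings(max_examples=300, derandomize=True)
    def test_idempotent_over_generated_tokens(self, num, letter, arm, stem):
        token = f"{stem}{num}{letter}{arm}"
        canonical = canonicalize_token(token)
        assert canonicalize_token(canonical) == canonical


class TestCatalog:
    def test_load_counts_and_idempotent_union(self, catalog, tmp_path):
        assert set(catalog.names_by_release) == {
            "aliases_rel20", "aliases_rel21", "aliases_rel22",
        }
        import importlib.resources as res

        src = res.files("bibliomir").joinpath("data/aliases_rel21.txt").read_text()
        p = tmp_path / "rel.txt"
        p.write_text(src)
        once = load_catalog([p])
        again = load_catalog([p, p])
        assert once.names_union == again.names_union

    def test_malformed_line_skipped_with_warning(self, tmp_path):
        p = tmp_path / "bad.txt"
        p.write_text("MI0000001\thsa-mir-21;\nnot a valid line\n")
        with pytest.warns(UserWarning, match="malformed"):
            cat = load_catalog([p])
        assert "hsa-mir-21" in cat.names_union

    def test_rename_resolves_through_alias_map(self, catalog):
        """A release renamed mir-203 to mir-203a; the old name still resolves."""
        assert catalog.resolve("hsa-mir-203") is not None
        assert "203a" in catalog.resolve("hsa-mir-203")
        assert validate_mention("miR-203", catalog)  # outdated but aliased

    @pytest.mark.parametrize(
        "canonical,expected",
        [("miR-21", True), ("miR-99999", False), ("let-7a", True), ("miR-3607-3p", True)],
    )
    def test_validate(self, catalog, canonical, expected):
        assert validate_mention(canonical, catalog) is expected

    def test_no_false_negatives_over_whole_catalog(self, catalog):
        """Every catalog name round-trips through canonicalise -> validate."""
        checked = 0
        for name in sorted(catalog.names_union):
            try:
                canonical = canonicalize_token(name)
            except ValueError:  # names outside the mention grammar (e.g. let-7a-1)
                continue
            assert validate_mention(canonical, catalog), name
            checked += 1
        assert checked > 50


class TestAnnualMatrix:
    def test_article_level_dedup(self, catalog):
        rec = BibRecord(
            record_id="r1",
            title="miR-21 in colon cancer",
            year=2020,
            abstract="We measured miR-21 and hsa-miR-21 repeatedly.",
        )
        matrix = annual_mirna_matrix(Corpus(records=[rec]), catalog)
        assert matrix.counts == {("miR-21", 2020): 1}

    def test_invalid_only_record_contributes_nothing(self, catalog):
        rec = BibRecord(record_id="r1", title="miR-99999 revisited", year=2020)
        matrix = annual_mirna_matrix(Corpus(records=[rec]), catalog)
        assert matrix.counts == {}

    def test_planted_incidence_recovered_exactly(self, synthetic_corpus, ground_truth, catalog):
        matrix = annual_mirna_matrix(synthetic_corpus, catalog)
        assert matrix.counts == ground_truth.mirna_year_counts

    def test_extraction_order_invariant(self, synthetic_corpus, catalog):
        matrix = annual_mirna_matrix(synthetic_corpus, catalog)
        reversed_corpus = Corpus(records=list(reversed(synthetic_corpus.records)))
        assert annual_mirna_matrix(reversed_corpus, catalog).counts == matrix.counts


class TestRanking:
    def test_mean_since_first_inclusive_span(self, catalog):
        """13 articles first seen 2008 with window end 2024 -> mean 13/17."""
        counts = {("miR-21", 2008): 1, ("miR-21", 2024): 12}
        from bibliomir.mirna import AnnualMirnaMatrix

        matrix = AnnualMirnaMatrix(counts=counts, window_end=2024)
        assert matrix.mean_since_first["miR-21"] == pytest.approx(13 / 17)

    def test_single_mirna_ranks_first_under_both_metrics(self):
        from bibliomir.mirna import AnnualMirnaMatrix

        matrix = AnnualMirnaMatrix(counts={("miR-1", 2020): 4}, window_end=2024)
        for metric in ("total", "mean_since_first"):
            assert rank_mirnas(matrix, metric=metric)["miRNA"].tolist() == ["miR-1"]

    def test_agrees_with_brute_force_sort(self):
        import numpy as np

        from bibliomir.mirna import AnnualMirnaMatrix

        rng = np.random.default_rng(99)
        counts = {}
        for k in range(50):
            mid = f"miR-{k}"
            for year in rng.choice(range(2008, 2025), size=3, replace=False):
                counts[(mid, int(year))] = int(rng.integers(1, 6))
        matrix = AnnualMirnaMatrix(counts=counts, window_end=2024)
        ranked = rank_mirnas(matrix, top_n=None, metric="total")

        totals, firsts = matrix.totals, matrix.first_year
        expected = sorted(totals, key=lambda m: (-totals[m], firsts[m], m))
        assert ranked["miRNA"].tolist() == expected


class TestNerQuality:
    def test_precision_and_recall_one_on_clean_planted_text(self, synthetic_corpus, ground_truth):
        """All planted ids recovered, nothing invalid accepted."""
        catalog = bundled_catalog()
        for rec in synthetic_corpus:
            mentions = extract_record_mentions(rec, catalog)
            valid = {m.canonical_id for m in mentions if m.valid}
            planted = ground_truth.mirna_mentions[rec.record_id]
            assert valid == planted  # recall and precision both exact
            for noise in ground_truth.noise_tokens[rec.record_id]:
                canonical = canonicalize_token(noise)
                assert not validate_mention(canonical, catalog)
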