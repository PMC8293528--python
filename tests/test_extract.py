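"""Extraction behavior: matching, normalization, sectioning, counting."""

import pytest

from residuefinder import (
    Document,
    abstract_of,
    count_mentions,
    extract,
    read_corpus_file,
    strip_bibliography,
)


def keys(result):
    return result.keys_in_order()


class TestExtract:
    def test_wnm_mutation(self, libraries):
        doc = Document("d", "the A64G mutant")
        assert keys(extract(doc, libraries["rf1"])) == ["A64G"]

    def test_spaced_residue_needs_rf2(self, libraries):
        doc = Document("d", "Ser 56 is phosphorylated")
        assert keys(extract(doc, libraries["rf1"])) == []
        assert keys(extract(doc, libraries["rf2"])) == ["S56"]
        assert keys(extract(doc, libraries["rf3"])) == ["S56"]

    def test_bare_capital_number_is_a_by_design_false_positive(self, libraries):
        doc = Document("d", "Bacteriophage T7 polymerase")
        assert keys(extract(doc, libraries["rf3"])) == ["T7"]

    def test_single_digit_switch(self, libraries):
        doc = Document("d", "residue G2 matters")
        assert keys(extract(doc, libraries["rf3"], allow_single_digit=False)) == []
        assert keys(extract(doc, libraries["rf3"], allow_single_digit=True)) == ["G2"]

    def test_mf_default_requires_two_digit_positions(self, libraries):
        doc = Document("d", "A4G and A64G were made")
        assert keys(extract(doc, libraries["mf"])) == ["A64G"]
        assert keys(extract(doc, libraries["rf1"])) == ["A4G", "A64G"]

    def test_full_name_and_synonym(self, libraries):
        doc = Document("d", "aspartic acid 464 and glutamate 210 were conserved")
        assert keys(extract(doc, libraries["rf2"])) == ["D464", "E210"]

    def test_arrow_mutation_only_in_rf3(self, libraries):
        doc = Document("d", "the S101→A substitution")
        assert keys(extract(doc, libraries["rf2"])) == ["S101"]
        assert keys(extract(doc, libraries["rf3"])) == ["S101A"]
        ascii_doc = Document("d", "the S101-->A substitution")
        assert keys(extract(ascii_doc, libraries["rf3"])) == ["S101A"]

    def test_mutation_takes_precedence_over_embedded_residue(self, libraries):
        doc = Document("d", "S56A abolished binding")
        result = extract(doc, libraries["rf3"])
        assert keys(result) == ["S56A"]
        assert len(result.matches) == 1

    def test_no_match_inside_words(self, libraries):
        doc = Document("d", "pH7 buffer and Kv1 channels")
        assert keys(extract(doc, libraries["rf2"])) == []

    def test_leading_zero_positions_are_noise(self, libraries):
        doc = Document("d", "sample S07 was frozen")
        assert "S7" not in extract(doc, libraries["rf2"]).unique_mentions

    def test_spans_and_raw_text_consistent(self, libraries):
        doc = Document("d", "Ala64 and Ser 56 and T7")
        result = extract(doc, libraries["rf3"])
        starts = [m.span[0] for m in result.matches]
        assert starts == sorted(starts)
        for m in result.matches:
            assert doc.text[m.span[0] : m.span[1]] == m.raw_text

    def test_nested_same_key_records_collapsed(self, libraries):
        # the bare "A64" inside "ALA64" must not double-count the event
        doc = Document("d", "ALA64 was mutated")
        result = extract(doc, libraries["rf3"])
        assert [m.raw_text for m in result.matches] == ["ALA64"]

    def test_empty_result_for_empty_library(self, libraries):
        from residuefinder.library import RegexLibrary

        doc = Document("d", "A64G")
        assert extract(doc, RegexLibrary("custom", [])).matches == []


class TestCountMentions:
    def test_single_versus_full(self, libraries):
        doc = Document("d", "S56 then S56 again and A64G")
        result = extract(doc, libraries["rf1"])
        assert count_mentions(result, "single") == {"S56": 1, "A64G": 1}
        assert count_mentions(result, "full") == {"S56": 2, "A64G": 1}

    def test_empty(self, libraries):
        doc = Document("d", "nothing here")
        result = extract(doc, libraries["rf1"])
        assert count_mentions(result, "single") == {}
        assert count_mentions(result, "full") == {}

    def test_bad_mode_rejected(self, libraries):
        result = extract(Document("d", ""), libraries["rf1"])
        with pytest.raises(ValueError):
            count_mentions(result, "both")


class TestStripBibliography:
    def test_tail_removed_when_heading_in_final_half(self):
        body = "x" * 400
        doc = Document("d", body + "\nReferences\n1. someone (1999) 141-146.")
        stripped = strip_bibliography(doc)
        # everything from the heading line onward is removed
        assert stripped.text == body + "\n"
        assert stripped.section_map["body"] == (0, 401)
        assert "References" not in stripped.text

    def test_no_heading_unchanged(self):
        doc = Document("d", "plain text with no reference section")
        assert strip_bibliography(doc).text == doc.text

    def test_early_heading_ignored(self):
        text = "intro\nReferences\n" + "y" * 400
        doc = Document("d", text)
        assert strip_bibliography(doc).text == text

    def test_heading_must_be_on_its_own_line(self):
        text = "z" * 400 + "\nsee the References section above\nmore text"
        doc = Document("d", text)
        assert strip_bibliography(doc).text == text


class TestSectioning:
    def test_abstract_of_prefers_section_map(self):
        doc = Document("d", "S56 here\n\nA64G there", {"abstract": (0, 8)})
        assert abstract_of(doc).text == "S56 here"

    def test_abstract_of_falls_back_to_first_blank_line(self):
        doc = Document("d", "S56 here\n\nA64G there")
        assert abstract_of(doc).text == "S56 here"

    def test_abstract_extraction_is_subset_of_full_text(self, libraries, small_corpus):
        documents, _, _ = small_corpus
        for doc in documents:
            full = {
                (m.span[0], m.mention.key)
                for m in extract(doc, libraries["rf3"]).matches
            }
            only = {
                (m.span[0], m.mention.key)
                for m in extract(abstract_of(doc), libraries["rf3"]).matches
            }
            assert only <= full


class TestReaders:
    def test_corpus_file_round_trip(self, tmp_path):
        path = tmp_path / "corpus.tsv"
        path.write_text(
            "doc1\tthe A64G mutant\ndoc2\tline one\\nline two with S56\n",
            encoding="utf-8",
        )
        documents = read_corpus_file(path)
        assert [d.doc_id for d in documents] == ["doc1", "doc2"]
        assert "\n" in documents[1].text

    def test_corpus_file_requires_tab(self, tmp_path):
        path = tmp_path / "corpus.tsv"
        path.write_text("doc1 no tab here\n", encoding="utf-8")
        with pytest.raises(ValueError, match="doc_id"):
            read_corpus_file(path)
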