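"""Offset arithmetic, sentence splitting, the BIO codec, and file formats."""

from __future__ import annotations

import pytest
from hypothesis import given, settings, strategies as st

from cnerkit.corpus import (
    AnnotatedDocument,
    CorpusError,
    EntityMention,
    TaggedSentence,
    TagScheme,
    bio_to_entities,
    entities_to_bio,
    read_annotations,
    read_conll,
    split_sentences,
    write_annotations,
    write_conll,
)
from cnerkit.synthetic import GeneratorConfig, generate_corpus

SCHEME = TagScheme()

cjk_text = st.text(alphabet="咳嗽发热。！？；，心房炎1a", min_size=1, max_size=60)


class TestSplitSentences:
    def test_two_terminated_sentences(self):
        assert split_sentences("咳嗽。发热。") == [("咳嗽。", 0), ("发热。", 3)]

    def test_trailing_unterminated_text(self):
        assert split_sentences("发热") == [("发热", 0)]

    def test_empty_text(self):
        assert split_sentences("") == []

    def test_worked_example_first_sentence_ends_at_first_period(self, example_doc):
        sents = split_sentences(example_doc.text)
        first, start = sents[0]
        assert start == 0
        assert first.endswith("。")
        assert len(first) - 1 == 17  # inclusive offset of the first 。

    @settings(derandomize=True, max_examples=200)
    @given(cjk_text)
    def test_concatenation_reconstructs_text(self, text):
        sents = split_sentences(text)
        assert "".join(s for s, _ in sents) == text
        offset = 0
        for s, start in sents:
            assert start == offset
            offset += len(s)


class TestEntityMention:
    def test_rejects_inverted_offsets(self):
        with pytest.raises(CorpusError):
            EntityMention("咳嗽", 5, 3, "symptom")

    def test_rejects_length_mismatch(self):
        with pytest.raises(CorpusError):
            EntityMention("咳嗽", 0, 5, "symptom")

    def test_rejects_unknown_category(self):
        with pytest.raises(CorpusError):
            EntityMention("咳嗽", 0, 1, "finding")


class TestBioCodec:
    def test_two_char_body_part_is_b_then_i(self):
        doc = AnnotatedDocument("d", "心房颤动。", {EntityMention("心房", 0, 1, "body_part")})
        (sent,) = entities_to_bio(doc, SCHEME)
        assert sent.labels == ["B-body", "I-body", "O", "O", "O"]

    def test_worked_example_cough_offsets(self, example_doc):
        labels = {}
        for sent in entities_to_bio(example_doc, SCHEME):
            for k, lab in enumerate(sent.labels):
                labels[sent.doc_offset + k] = lab
        assert labels[21] == "B-symptom"
        assert labels[22] == "I-symptom"

    def test_empty_entity_set_is_all_outside(self):
        doc = AnnotatedDocument("d", "患者咳嗽。", set())
        (sent,) = entities_to_bio(doc, SCHEME)
        assert sent.labels == ["O"] * 5

    def test_overlapping_entities_rejected(self):
        doc = AnnotatedDocument(
            "d",
            "脂肪肝病史。",
            {EntityMention("脂肪肝", 0, 2, "diagnosis"), EntityMention("肝", 2, 2, "body_part")},
        )
        with pytest.raises(CorpusError, match="overlap"):
            entities_to_bio(doc, SCHEME)

    def test_entity_crossing_sentence_boundary_rejected(self):
        doc = AnnotatedDocument("d", "咳。嗽热。", {EntityMention("。嗽", 1, 2, "symptom")})
        with pytest.raises(CorpusError, match="crosses"):
            entities_to_bio(doc, SCHEME)

    def test_decode_simple_run(self):
        sent = TaggedSentence("心房颤动", ["B-body", "I-body", "O", "O"])
        assert bio_to_entities(sent, SCHEME) == {EntityMention("心房", 0, 1, "body_part")}

    def test_all_outside_decodes_to_empty(self):
        sent = TaggedSentence("心房颤动", ["O"] * 4)
        assert bio_to_entities(sent, SCHEME) == set()

    def test_dangling_inside_is_repaired_to_begin(self):
        sent = TaggedSentence("查体", ["I-test", "I-test"])
        assert bio_to_entities(sent, SCHEME) == {EntityMention("查体", 0, 1, "test")}

    def test_unknown_label_rejected(self):
        sent = TaggedSentence("查体", ["B-test", "X-test"])
        with pytest.raises(CorpusError, match="unknown label"):
            bio_to_entities(sent, SCHEME)

    def test_doc_offset_shifts_decoded_spans(self):
        sent = TaggedSentence("心房", ["B-body", "I-body"], doc_offset=10)
        (ent,) = bio_to_entities(sent, SCHEME)
        assert (ent.pos_b, ent.pos_e) == (10, 11)

    @settings(derandomize=True, max_examples=60)
    @given(st.lists(st.sampled_from(SCHEME.labels), min_size=1, max_size=12))
    def test_decode_agrees_with_run_scanner_oracle(self, labels):
        """Any label sequence decodes exactly like an independent scanner that
        first repairs dangling I-x to B-x, then takes maximal B I* runs."""
        chars = "字" * len(labels)
        # oracle: repair pass
        repaired = []
        prev_cat = None
        for lab in labels:
            prefix, cat = TagScheme.parse_label(lab)
            if prefix == "I" and cat != prev_cat:
                repaired.append(("B", cat))
            else:
                repaired.append((prefix, cat))
            prev_cat = cat if prefix != "O" else None
        # oracle: maximal runs
        expected = set()
        k = 0
        while k < len(repaired):
            prefix, cat = repaired[k]
            if prefix == "B":
                end = k
                while end + 1 < len(repaired) and repaired[end + 1] == ("I", cat):
                    end += 1
                expected.add(EntityMention(chars[k : end + 1], k, end, cat))
                k = end + 1
            else:
                k += 1
        assert bio_to_entities(TaggedSentence(chars, list(labels)), SCHEME) == expected

    def test_round_trip_on_synthetic_corpus(self, small_corpus):
        for doc in small_corpus:
            decoded = set()
            for sent in entities_to_bio(doc, SCHEME):
                decoded |= bio_to_entities(sent, SCHEME)
            assert decoded == doc.entities


class TestTagScheme:
    def test_label_inventory(self):
        assert SCHEME.n_labels == 11
        assert SCHEME.labels[0] == "O"
        assert set(SCHEME.labels) == {
            "O",
            "B-symptom", "I-symptom", "B-test", "I-test",
            "B-diagnosis", "I-diagnosis", "B-treatment", "I-treatment",
            "B-body", "I-body",
        }


class TestAnnotationTsv:
    def test_worked_example_rows_are_substring_consistent(self, example_doc):
        for ent in example_doc.entities:
            assert example_doc.text[ent.pos_b : ent.pos_e + 1] == ent.mention

    def test_read_write_round_trip(self, tmp_path, example_doc):
        txt = tmp_path / "doc.txt"
        tsv = tmp_path / "doc.tsv"
        txt.write_text(example_doc.text, encoding="utf-8")
        tsv.write_text(write_annotations(example_doc), encoding="utf-8")
        loaded = read_annotations(txt, tsv)
        assert loaded.entities == example_doc.entities
        assert write_annotations(loaded) == write_annotations(example_doc)

    def test_substring_mismatch_reported_with_offsets(self, tmp_path):
        (tmp_path / "doc.txt").write_text("患者咳嗽。", encoding="utf-8")
        (tmp_path / "doc.tsv").write_text("发热\t2\t3\tsymptom\n", encoding="utf-8")
        with pytest.raises(CorpusError, match=r"发热.*咳嗽"):
            read_annotations(tmp_path / "doc.txt", tmp_path / "doc.tsv")

    def test_inverted_offsets_rejected_with_line_number(self, tmp_path):
        (tmp_path / "doc.txt").write_text("患者咳嗽。", encoding="utf-8")
        (tmp_path / "doc.tsv").write_text("咳嗽\t3\t2\tsymptom\n", encoding="utf-8")
        with pytest.raises(CorpusError, match=":1:"):
            read_annotations(tmp_path / "doc.txt", tmp_path / "doc.tsv")

    def test_malformed_row_rejected_with_line_number(self, tmp_path):
        (tmp_path / "doc.txt").write_text("患者咳嗽。", encoding="utf-8")
        (tmp_path / "doc.tsv").write_text("咳嗽\t2\t3\n", encoding="utf-8")
        with pytest.raises(CorpusError, match=":1:"):
            read_annotations(tmp_path / "doc.txt", tmp_path / "doc.tsv")


class TestConll:
    def test_single_sentence_rendering(self):
        out = write_conll([TaggedSentence("心房", ["B-body", "I-body"])])
        assert out == "心\tB-body\n房\tI-body\n"

    def test_empty_corpus_renders_empty_file(self):
        assert write_conll([]) == ""

    def test_round_trip_on_synthetic_corpus(self, lexicons):
        train_lex, _ = lexicons
        docs = generate_corpus(GeneratorConfig(seed=3, n_documents=10, lexicons=train_lex))
        sents = [s for d in docs for s in entities_to_bio(d, SCHEME)]
        assert len(sents) >= 100
        loaded = read_conll(write_conll(sents), SCHEME)
        assert [(s.chars, s.labels) for s in loaded] == [(s.chars, s.labels) for s in sents]

    def test_ragged_line_rejected(self):
        with pytest.raises(CorpusError, match="line 2"):
            read_conll("心\tB-body\n房子\tI-body\n", SCHEME)
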