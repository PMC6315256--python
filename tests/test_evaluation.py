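"""Strict matching, micro-pooled P/R/F1, the error partition, cross-validation."""

from __future__ import annotations

import numpy as np
import pytest

from cnerkit.corpus import EntityMention
from cnerkit.dictionary import build_dictionary, max_forward_match
from cnerkit.evaluation import classify_errors, cross_validate, evaluate, strict_equal
from cnerkit.synthetic import GeneratorConfig, generate_corpus, generate_lexicons


def ent(mention, pos_b, category="symptom"):
    return EntityMention(mention, pos_b, pos_b + len(mention) - 1, category)


class TestStrictEqual:
    def test_identical_mentions_match(self):
        assert strict_equal(ent("咳嗽", 21), ent("咳嗽", 21))

    def test_offset_shift_breaks_equality(self):
        assert not strict_equal(ent("咳嗽", 21), ent("咳嗽", 22))

    def test_category_difference_breaks_equality(self):
        assert not strict_equal(ent("头痛", 3, "symptom"), ent("头痛", 3, "diagnosis"))

    def test_mention_text_difference_breaks_equality(self):
        a = EntityMention("咳嗽", 21, 22, "symptom")
        b = EntityMention("发热", 21, 22, "symptom")
        assert not strict_equal(a, b)


class TestEvaluate:
    def test_self_evaluation_is_perfect(self, example_doc):
        gold = {"doc": set(example_doc.entities)}
        report = evaluate(gold, gold)
        assert (report.overall.precision, report.overall.recall, report.overall.f1) == (1, 1, 1)
        assert report.errors.counts == {"GT-P": 0, "P-GT": 0, "INTERSECT": 0}

    def test_disjoint_sets_score_zero(self):
        pred = {"doc": {ent("咳嗽", 0)}}
        gold = {"doc": {ent("发热", 10)}}
        report = evaluate(pred, gold)
        assert report.overall.f1 == 0.0

    def test_printed_arithmetic_case(self):
        gold = {"doc": {ent(m, 10 * k) for k, m in enumerate(["咳嗽", "发热", "头痛", "乏力", "盗汗"])}}
        pred = {"doc": {ent(m, 10 * k) for k, m in enumerate(["咳嗽", "发热", "头痛"])} | {ent("眩晕", 90)}}
        report = evaluate(pred, gold)
        assert report.overall.precision == pytest.approx(0.75)
        assert report.overall.recall == pytest.approx(0.6)
        assert report.overall.f1 == pytest.approx(2 * 0.75 * 0.6 / 1.35)

    def test_category_counts_partition_overall(self, example_doc):
        pred = {"doc": set(list(sorted(example_doc.entities, key=EntityMention.sort_key))[:10])}
        gold = {"doc": set(example_doc.entities)}
        report = evaluate(pred, gold)
        assert sum(s.n_correct for s in report.per_category.values()) == report.overall.n_correct
        assert sum(s.n_gold for s in report.per_category.values()) == report.overall.n_gold

    def test_document_id_mismatch_rejected(self):
        with pytest.raises(ValueError, match="ids differ"):
            evaluate({"a": set()}, {"b": set()})


class TestClassifyErrors:
    def test_partial_overlap_is_intersect(self):
        gold = {EntityMention("脂肪肝", 4, 6, "diagnosis")}
        pred = {EntityMention("肝", 6, 6, "body_part")}
        part = classify_errors(pred, gold)
        assert part.counts == {"GT-P": 0, "P-GT": 0, "INTERSECT": 1}
        group = part.intersect[0]
        assert [e.mention for e in group.gold] == ["脂肪肝"]
        assert [e.mention for e in group.predicted] == ["肝"]

    def test_unmatched_gold_without_overlap_is_gt_p(self):
        part = classify_errors(set(), {ent("低血糖", 0, "diagnosis")})
        assert part.counts == {"GT-P": 1, "P-GT": 0, "INTERSECT": 0}

    def test_unmatched_prediction_without_overlap_is_p_gt(self):
        part = classify_errors({ent("冠心病", 0, "diagnosis")}, set())
        assert part.counts == {"GT-P": 0, "P-GT": 1, "INTERSECT": 0}

    def test_exact_matches_excluded_from_partition(self):
        both = {ent("咳嗽", 0)}
        part = classify_errors(both, both)
        assert part.counts == {"GT-P": 0, "P-GT": 0, "INTERSECT": 0}

    def test_one_gold_split_into_two_predictions_counts_once(self):
        gold = {EntityMention("糖尿病肾病", 0, 4, "diagnosis")}
        pred = {
            EntityMention("糖尿病", 0, 2, "diagnosis"),
            EntityMention("肾病", 3, 4, "diagnosis"),
        }
        part = classify_errors(pred, gold)
        assert part.counts["INTERSECT"] == 1
        assert len(part.intersect[0].predicted) == 2

    def test_partition_is_exhaustive_and_exclusive(self):
        rng = np.random.default_rng(2)
        cats = ["symptom", "test", "diagnosis", "treatment", "body_part"]
        for _ in range(30):
            def random_set():
                out = set()
                for _ in range(rng.integers(0, 8)):
                    b = int(rng.integers(0, 40))
                    length = int(rng.integers(1, 5))
                    out.add(EntityMention("字" * length, b, b + length - 1,
                                          cats[rng.integers(5)]))
                return out

            pred, gold = random_set(), random_set()
            part = classify_errors(pred, gold)
            part_gold = {e for _, e in part.gt_p} | {
                e for grp in part.intersect for e in grp.gold
            }
            part_pred = {e for _, e in part.p_gt} | {
                e for grp in part.intersect for e in grp.predicted
            }
            assert part_gold == gold - pred
            assert part_pred == pred - gold


class TestCrossValidate:
    @pytest.fixture(scope="class")
    def tiny_docs(self):
        # uniform mix over a small lexicon: every term occurs in every fold,
        # so a dictionary learned from any training fold is near-perfect
        train_lex, _ = generate_lexicons(21, sizes=5)
        config = GeneratorConfig(
            seed=21, n_documents=10, lexicons=train_lex,
            category_mix={c: 0.2 for c in ("symptom", "test", "diagnosis", "treatment", "body_part")},
        )
        return generate_corpus(config), train_lex

    @staticmethod
    def dictionary_trainer(train_docs):
        d = build_dictionary(
            (e.mention, e.category) for doc in train_docs for e in sorted(doc.entities, key=EntityMention.sort_key)
        )
        return lambda doc: max_forward_match(doc.text, d)

    def test_every_document_held_out_exactly_once(self, tiny_docs):
        docs, _ = tiny_docs
        result = cross_validate(docs, 2, self.dictionary_trainer, seed=0)
        flat = sorted(i for fold in result["folds"] for i in fold)
        assert flat == list(range(10))
        assert [len(f) for f in result["folds"]] == [5, 5]

    def test_same_seed_gives_identical_folds(self, tiny_docs):
        docs, _ = tiny_docs
        a = cross_validate(docs, 5, self.dictionary_trainer, seed=3)
        b = cross_validate(docs, 5, self.dictionary_trainer, seed=3)
        assert a["folds"] == b["folds"]
        assert a["fold_f1"] == b["fold_f1"]

    def test_learnable_corpus_scores_high(self, tiny_docs):
        docs, _ = tiny_docs
        result = cross_validate(docs, 2, self.dictionary_trainer, seed=1)
        assert result["mean_f1"] >= 0.95

    def test_corpus_smaller_than_k_rejected(self, tiny_docs):
        docs, _ = tiny_docs
        with pytest.raises(ValueError):
            cross_validate(docs[:3], 4, self.dictionary_trainer)
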