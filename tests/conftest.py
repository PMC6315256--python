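"""Shared fixtures: the worked example and small seeded synthetic corpora."""

from __future__ import annotations

import pytest

from cnerkit.corpus import TagScheme, entities_to_bio
from cnerkit.features import seg_bmes
from cnerkit.segmenter import LexiconSegmenter
from cnerkit.synthetic import (
    GeneratorConfig,
    generate_corpus,
    generate_lexicons,
    segmentation_lexicon,
)
from cnerkit.worked_example import example_dictionary_pairs, example_document


@pytest.fixture(scope="session")
def example_doc():
    return example_document()


@pytest.fixture(scope="session")
def example_dict_pairs():
    return example_dictionary_pairs()


@pytest.fixture(scope="session")
def lexicons():
    """(train, held-out) category lexicons, seed 7."""
    return generate_lexicons(7)


@pytest.fixture(scope="session")
def small_corpus(lexicons):
    """Eight annotated synthetic documents over the train lexicon."""
    train_lex, _ = lexicons
    return generate_corpus(GeneratorConfig(seed=7, n_documents=8, lexicons=train_lex))


@pytest.fixture(scope="session")
def small_sentences(small_corpus):
    scheme = TagScheme()
    return [s for d in small_corpus for s in entities_to_bio(d, scheme)]


@pytest.fixture(scope="session")
def segmenter(lexicons):
    train_lex, held_lex = lexicons
    return LexiconSegmenter.from_pairs(segmentation_lexicon(train_lex, held_lex))


@pytest.fixture(scope="session")
def seg_fn(segmenter):
    """Sentence -> per-character BMES tags, via the built-in segmenter."""

    def fn(chars: str) -> list[str]:
        return seg_bmes([w for w, _ in segmenter(chars)])

    return fn
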