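"""Train the feature-based CRF and compare feature families.

Trains two CRFs on a small synthetic corpus — one with bag-of-characters
features only, one adding projected POS tags, character types, and the
position-in-sentence bucket — and scores both on held-out documents with
strict entity-level matching.  Richer feature sets should not hurt.
"""

from cnerkit.corpus import TagScheme, entities_to_bio
from cnerkit.crf_tagger import predict_document, train_crf
from cnerkit.evaluation import evaluate
from cnerkit.features import FeatureConfig
from cnerkit.segmenter import LexiconSegmenter
from cnerkit.synthetic import (
    GeneratorConfig, generate_corpus, generate_lexicons, segmentation_lexicon,
)

train_lex, held_lex = generate_lexicons(seed=7)
train_docs = generate_corpus(GeneratorConfig(seed=7, n_documents=15, lexicons=train_lex))
test_docs = generate_corpus(GeneratorConfig(seed=8, n_documents=5, lexicons=train_lex))
sentences = [s for d in train_docs for s in entities_to_bio(d, TagScheme())]
segmenter = LexiconSegmenter.from_pairs(segmentation_lexicon(train_lex, held_lex))
gold = {d.doc_id: set(d.entities) for d in test_docs}

for families in (("boc",), ("boc", "pos", "ct", "pocis")):
    model = train_crf(sentences, FeatureConfig(families=families), segmenter)
    pred = {d.doc_id: predict_document(model, d.text, segmenter) for d in test_docs}
    report = evaluate(pred, gold)
    o = report.overall
    print(f"{'+'.join(families):<20} P={o.precision:.4f} R={o.recall:.4f} F1={o.f1:.4f}")
# Strict F1 counts an entity as correct only when mention, both offsets,
# and category all equal a gold entity's.
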