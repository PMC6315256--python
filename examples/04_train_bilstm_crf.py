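"""Train the bidirectional peephole LSTM-CRF tagger at desk scale.

Pipeline: (1) pretrain skip-gram character embeddings on a separate
unlabeled synthetic draw — the pretraining corpus defines the character
inventory, so characters unseen in the labeled data still get useful
vectors; (2) train the BiLSTM-CRF end to end with Adam, dropout on the
context representation, and early stopping on held-out strict F1.
Scaled down (hidden 16, embedding 32) so it runs in about a minute.
"""

from cnerkit.bilstm import NeuralConfig, predict_bilstm_crf, train_bilstm_crf
from cnerkit.corpus import TagScheme, entities_to_bio
from cnerkit.embeddings import train_char_embeddings
from cnerkit.evaluation import evaluate
from cnerkit.features import seg_bmes
from cnerkit.segmenter import LexiconSegmenter
from cnerkit.synthetic import (
    GeneratorConfig, generate_corpus, generate_lexicons, segmentation_lexicon,
)

train_lex, held_lex = generate_lexicons(seed=7)
train_docs = generate_corpus(GeneratorConfig(seed=7, n_documents=15, lexicons=train_lex))
test_docs = generate_corpus(GeneratorConfig(seed=8, n_documents=5, lexicons=train_lex))
unlabeled = generate_corpus(GeneratorConfig(seed=9, n_documents=30, lexicons=train_lex))

table = train_char_embeddings(
    "".join(d.text for d in unlabeled), dim=32, epochs=2, seed=11
)
print(f"pretrained {table.dim}-dim embeddings for {len(table.vocab)} characters")

segmenter = LexiconSegmenter.from_pairs(segmentation_lexicon(train_lex, held_lex))
seg_fn = lambda chars: seg_bmes([w for w, _ in segmenter(chars)])
scheme = TagScheme()
sentences = [s for d in train_docs for s in entities_to_bio(d, scheme)]

# a larger learning rate than the corpus-scale default keeps this small
# demo inside a minute; the acceptance experiment uses the standard 4e-4
config = NeuralConfig(embed_dim=32, hidden=16, epochs=40, patience=15, lr=3e-3)
model = train_bilstm_crf(
    sentences, seg_fn, config, seed=42,
    pretrained=table.matrix, pretrained_vocab=table.vocab,
)
for h in model.training_history[-3:]:
    print(f"  epoch {h['epoch']:>2}: train loss {h['train_loss']:.3f}, dev F1 {h['dev_f1']:.3f}")

pred = {}
for d in test_docs:
    mentions = set()
    for sent in entities_to_bio(d, scheme):
        mentions |= predict_bilstm_crf(model, sent.chars, seg_fn(sent.chars),
                                       doc_offset=sent.doc_offset)
    pred[d.doc_id] = mentions
report = evaluate(pred, {d.doc_id: set(d.entities) for d in test_docs})
o = report.overall
print(f"held-out strict P={o.precision:.4f} R={o.recall:.4f} F1={o.f1:.4f}")
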