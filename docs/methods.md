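# Methods

This note documents the models implemented in cnerkit, the choices behind
their defaults, what the synthetic data generator does and does not
emulate, and the numerical conventions that make results reproducible.

## Data model and the BIO codec

Documents are plain Unicode text; entities are `(mention, pos_b, pos_e,
category)` rows with 0-based offsets inclusive on both ends, counted in
code points. Every character — CJK, punctuation, digit, Latin letter —
occupies exactly one position; there is no tokenization at the offset
level. This is the only convention under which gold offsets in CCKS-style
annotation files reconcile with the raw text, and the reader validates
`text[pos_b..pos_e] == mention` for every row it ingests.

Sentences end at 。！？； or a newline; concatenating sentences reproduces
the document byte-for-byte, so per-sentence tagging and document-level
offsets stay consistent. Gold entities are assumed non-overlapping and may
not cross sentence boundaries (violations are reported, not guessed
around).

The tag scheme over the five clinical categories is the 11-label BIO
inventory, fixed in the order `[O, B-symptom, I-symptom, B-test, I-test,
B-diagnosis, I-diagnosis, B-treatment, I-treatment, B-body, I-body]` so
that label indices are stable across runs. Decoding accepts any label
sequence: a dangling I-x (one not continuing a run of the same category) is
repaired to B-x, the standard recall-preserving CoNLL convention, which
makes encode/decode exact inverses on legal input and total on illegal
input.

## Dictionary baseline

The term dictionary maps each term to exactly one category
(first-source-wins on conflicts, with a logged warning). Maximum forward
matching scans the whole document left to right, probing lengths from
`max_len` down at each position against the hash map — a trie would be an
optimization, not a behavioral change. Matching is exact on code points
with no width normalization, because any normalization would desynchronize
offsets from the raw text. Matches may in principle span sentence
boundaries; since no term contains a sentence terminator this does not
arise in practice.

## Linear-chain CRF

State features are (feature-string × label) indicators; transitions are
label-pair indicators with no observation dependence. There are no
explicit start/stop transition weights and no hard-coded BIO legality —
the transition matrix learns it. The four feature families:

* **BOC** — character unigrams over the ±2 window (`C-2..C+2`) plus the two
  adjacent bigrams `C-1C0`, `C0C+1`. Out-of-window positions yield `<S>`
  / `<E>` sentinels. The bigram templates can be switched off.
* **POS** — the containing word's part-of-speech tag projected onto each
  character, same window. Segmentation/POS come from a pluggable segmenter
  contract (any callable producing `(word, pos)` tokens that reconstruct
  the sentence); the built-in default is greedy longest-match over a word
  lexicon, which is exact on the synthetic corpus and replaceable by any
  external segmenter for real text.
* **CT** — character type: D digits (ASCII + full-width), L Latin letters
  (both widths), S ending punctuation (。！？； and ASCII `.!?;`), P paired
  punctuation (brackets, quotes, 、，： and ASCII equivalents), W everything
  else. Total over the BMP by construction.
* **POCIS** — position bucket: FIRST/LAST at the sentence edges, else the
  quartile of `index/length`. Bucketing keeps the vocabulary bounded and
  sentence-length invariant.

With all four families every position emits 18 features (7 + 5 + 5 + 1).

Training minimizes the L2-penalized negative conditional log-likelihood
(`C = 1.0` by default) with L-BFGS (memory 10, up to 200 iterations,
projected-gradient tolerance 1e-5), starting from zero weights — the
objective is convex, so the optimum is seed-free and training is
deterministic given the corpus. The gradient is expected minus empirical
feature counts from exact forward–backward marginals. Two implementations
exist: a per-sentence reference version, and a padded, batch-vectorized
version used by the trainer; a test pins them equal to ~1e-14. Features
unseen at training time are dropped at prediction time, so unseen
characters degrade gracefully to sentinel/type/position evidence.

## Bidirectional peephole LSTM-CRF

The LSTM unit implements the peephole equations exactly as printed in the
module docstring: the input and forget gates see `c_{t-1}`, the output gate
sees `c_t`, and the peephole weights are diagonal (vectors). Many
"BiLSTM-CRF" codebases omit the peepholes; they are kept here
deliberately, and the gradient check covers them.

Input representation: `x_t = [embedding(c_t) ; onehot(BMES_t)]`, with BMES
word-boundary tags from the same pluggable segmenter. OOV characters use a
dedicated UNK row. Both directions start from zero hidden/cell states;
their outputs are concatenated per position, passed through (inverted)
dropout during training, and linearly projected to the 11 label scores.
The CRF output layer *is* the crf module — same log-partition, same
Viterbi — so the enumeration oracles that validate the feature CRF validate
the neural model's structured layer too.

Training: Adam (lr 4e-4, β = 0.9/0.999), dropout 0.5 on the context rows,
mini-batches of 8 (gradients averaged), global-norm clipping at 5.0, early
stopping on held-out strict F1 with the best weights retained. All
randomness — init, batch order, dropout masks, dev split — flows from one
seed, so identical seeds give identical weights. Backpropagation through
time is hand-derived in float64 and checked end to end against central
finite differences (tolerance 1e-4; the worst components are those whose
true gradient is ~1e-7, where the quotient is dominated by cancellation
noise).

Initialization: uniform(−0.1, 0.1) for matrices and peephole vectors, zero
biases except the forget-gate bias at +1.0 (the standard stabilizer for
gradient flow early in training).

Defaults are embedding 100 / hidden 100, the standard configuration for
this architecture on corpus-scale Chinese clinical data. The desk-scale
experiments in the test suite use hidden 25 and embedding 50 so the full
pipeline trains in minutes on one CPU; the tests' conclusions are about
correctness and recoverability, not about corpus-scale accuracy.

## Character embeddings

Skip-gram with negative sampling over single characters (clinical Chinese
is embedded at the character level, so no segmentation is involved):
window 5, 5 negatives drawn from the unigram^0.75 distribution, 5 epochs of
plain SGD (lr 0.025), all seeded. The trained table's UNK row is the mean
vector. A seeded uniform(±0.05) random table is available so the neural
model is testable without pretraining.

One pipeline decision matters: when pretrained embeddings are supplied to
the neural model, the pretraining corpus defines the character vocabulary
(labeled-data characters are added on top). Rare-category terms contribute
so few labeled occurrences that many of their characters never appear in a
small labeled set; if those characters collapsed to UNK at inference, the
rare categories would be systematically misclassified. With the unlabeled
corpus defining the inventory, such characters carry pretrained vectors
that already cluster by co-occurrence, and the desk-scale recovery
experiments depend on this (diagnosis and treatment go from unrecoverable
to fully recovered).

## Evaluation

Strict equivalence requires all four fields to match; since the entity
dataclass is hashable on exactly those fields, set intersection implements
the metric directly. Counts are micro-pooled across documents (summed,
then divided), the direct reading of the set-cardinality definitions; F1
is 0 when P + R = 0. Per-category scores restrict both sides to the
category, so per-category intersection counts sum to the overall count.

The error partition removes exact matches, then classifies at the entity
level: gold entities with no character overlap to any prediction are GT-P,
predictions with no gold overlap are P-GT, and the remaining entities form
INTERSECT groups — connected components of the span-overlap graph — so an
entity overlapping several counterparts is counted once, and the partition
is exclusive and exhaustive (property-tested).

Cross-validation shuffles documents once with the given seed and cuts k
contiguous folds; each fold is held out in turn and the per-fold strict F1
scores are averaged.

## Synthetic corpus generator

The generator emulates the *structure* of annotated Chinese EHR data, not
its language: four numbered narrative sections per document; sentences of
1–3 clauses built from slot templates with clinical connective phrasing
(plus CJK punctuation, digits, and Latin units in filler clauses); entity
slots filled from category lexicons and recorded with exact offsets; a
skewed default category mix (body part 35%, test 32%, symptom 26%,
treatment 4%, diagnosis 3%) of the kind real corpora show. The seed is
mandatory and fully determines the corpus.

Lexicon terms are 2–6-character strings over per-category slices of a
~500-code-point CJK pool that excludes every template character. Terms —
and characters — are therefore disjoint across categories. This is the
central difficulty dial: category identity is recoverable from character
evidence, which is what makes a ~500-sentence corpus sufficient for both
taggers to reach high strict F1, including on terms held out from the
lexicon (the 80/20 train/held-out term split exists for exactly that
probe). Real clinical text is harsher — characters are shared across
categories and the same surface form can be annotated differently by
context — so passing the recovery experiments demonstrates implementation
correctness, not expected performance on real EHRs. The `ambiguity` knob
reintroduces a slice of that difficulty by reusing symptom-pool surface
forms under the diagnosis category in diagnosis templates.

Two structural guarantees support the oracles: templates always place a
non-lexicon character between adjacent entity slots, and template
characters never occur inside terms; together they imply that a dictionary
holding the full lexicon recovers every generated entity by maximum
forward matching, with no false positives.

## Numerical conventions and edge cases

* All probabilistic computation is in log space, float64; log-sum-exp is
  max-shifted and stable for scores to at least ±700.
* Viterbi breaks ties toward the lower label index at every backtrack step,
  so the all-zero score matrix decodes to all-O.
* Empty sentences predict empty mention sets; empty corpora are errors.
* Model files are single versioned `.npz` containers (weights, vocabulary,
  scheme, configuration) with bit-exact round-trip, shared in layout
  between the CRF and the neural model.
* Experiment sizes in the test suite (~500 training sentences, 10 held-out
  documents, hidden 25) were chosen once as the desk-scale conditions; the
  acceptance thresholds (strict F1 ≥ 0.95, gradient tolerances 1e-6 /
  1e-4, enumeration agreement 1e-8) are asserted at those sizes.

## Known limitations

* The built-in segmenter is a lexicon matcher; on real text a proper
  segmenter (e.g. jieba-compatible output) should be plugged in via the
  segmenter contract.
* No support for nested, discontinuous, or overlapping entities, byte
  offsets, or standoff formats.
* The CRF has no observation-dependent transition features; the neural
  model has no character-CNN subword path and no GPU path — it is a
  correctness-first float64 implementation sized for desk-scale corpora.
* Synthetic-corpus results do not transfer to real EHR accuracy claims;
  the generator's disjoint character pools make the task deliberately
  learnable at small sample sizes.
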