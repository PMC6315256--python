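"""Strict evaluation and the three-way error partition.

Runs the dictionary baseline with a deliberately incomplete dictionary
(training lexicon only) on documents that also contain held-out terms, then
partitions the errors: GT-P (gold entities entirely missed), P-GT
(predictions with no gold overlap), and INTERSECT (overlapping but not
identical — boundary or category disagreements).
"""

from cnerkit.dictionary import build_dictionary, max_forward_match
from cnerkit.evaluation import evaluate
from cnerkit.synthetic import (
    GeneratorConfig, generate_corpus, generate_lexicons, full_lexicon_pairs,
)

train_lex, held_lex = generate_lexicons(seed=7)
merged = {cat: train_lex[cat] + held_lex[cat] for cat in train_lex}
docs = generate_corpus(GeneratorConfig(seed=12, n_documents=15, lexicons=merged))

dictionary = build_dictionary(full_lexicon_pairs(train_lex))  # held-out terms missing
pred = {d.doc_id: max_forward_match(d.text, dictionary) for d in docs}
gold = {d.doc_id: set(d.entities) for d in docs}

report = evaluate(pred, gold)
print(report.summary())
print()
for doc_id, ent in report.errors.gt_p[:3]:
    print(f"GT-P      {ent.mention} ({ent.category}) — not in the dictionary")
for group in report.errors.intersect[:3]:
    g = " + ".join(e.mention for e in group.gold)
    p = " + ".join(e.mention for e in group.predicted)
    print(f"INTERSECT {g}  vs  {p}")
# GT-P errors here are exactly the held-out terms the dictionary lacks;
# INTERSECT arises when a shorter known term overlaps a longer gold one.
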