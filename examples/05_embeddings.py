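"""Character-embedding training and what it learns.

Trains skip-gram-with-negative-sampling embeddings on unlabeled synthetic
clinical text and shows that characters from the same category pool (which
co-occur inside terms and templates) end up closer in cosine similarity
than characters from different pools.
"""

import numpy as np

from cnerkit.embeddings import train_char_embeddings
from cnerkit.synthetic import GeneratorConfig, generate_corpus, generate_lexicons

train_lex, _ = generate_lexicons(seed=7, sizes=30)
docs = generate_corpus(GeneratorConfig(seed=9, n_documents=30, lexicons=train_lex))
text = "".join(d.text for d in docs)

table = train_char_embeddings(text, dim=32, window=5, negatives=5, epochs=3, seed=11)
print(f"corpus: {len(text)} characters; vocabulary: {len(table.vocab)}")
print("per-epoch negative-sampling loss:", [round(float(l), 3) for l in table.epoch_losses])

rng = np.random.default_rng(0)


def cos(a: str, b: str) -> float:
    u, v = table.vector(a), table.vector(b)
    return float(u @ v / (np.linalg.norm(u) * np.linalg.norm(v)))


def pool_chars(cat: str) -> list[str]:
    return sorted({ch for term in train_lex[cat] for ch in term if ch in table.vocab})


within, between = [], []
cats = list(train_lex)
for cat in cats:
    chars = pool_chars(cat)
    for _ in range(200):
        a, b = rng.choice(chars, size=2, replace=False)
        within.append(cos(a, b))
for _ in range(500):
    ca, cb = rng.choice(cats, size=2, replace=False)
    within_a, within_b = pool_chars(ca), pool_chars(cb)
    between.append(cos(rng.choice(within_a), rng.choice(within_b)))

print(f"mean cosine within a category pool : {np.mean(within):+.3f}")
print(f"mean cosine between category pools : {np.mean(between):+.3f}")
# Characters sharing a category co-occur inside terms and templates, so the
# embedding space pulls them together: within-pool similarity exceeds
# between-pool similarity, recovering the corpus' co-occurrence structure.
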