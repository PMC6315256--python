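"""Seeded generator of synthetic annotated Chinese-style clinical documents.

The generator emulates the structure of CCKS-style annotated EHR data so
that every recognizer, the evaluator, and all oracles can run at desk scale
with no external corpus:

* each document has 4 narrative sections (general items, medical history,
  diagnosis and treatment, discharge note), numbered like real progress
  notes;
* clauses are built from slot templates with clinical connective phrasing,
  CJK punctuation, digits, and Latin units; each entity slot is filled with
  a lexicon term and recorded with exact 0-based inclusive offsets;
* the default category mix is skewed the way real corpora are
  (body_part 35%, test 32%, symptom 26%, treatment 4%, diagnosis 3%);
* category lexicons are random 2-6-character terms over per-category
  character pools that are disjoint from each other and from every template
  character.  Disjoint pools keep held-out-term generalization learnable
  from character evidence at desk scale; a template always contributes at
  least one non-lexicon character between adjacent entities, so a dictionary
  holding the full lexicon recovers every generated entity by maximum
  forward matching.

The language is deliberately not clinically realistic — offsets, structure,
and controllable difficulty are the point.  An ambiguity knob can inject
terms that appear under two categories in different templates, mimicking
the real annotation difficulty of context-dependent entity types.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from cnerkit.corpus import AnnotatedDocument, CATEGORIES, EntityMention

DEFAULT_CATEGORY_MIX = {
    "body_part": 0.35,
    "test": 0.32,
    "symptom": 0.26,
    "treatment": 0.04,
    "diagnosis": 0.03,
}

#: Clause templates per category; {X} marks the entity slot.
TEMPLATES: dict[str, list[str]] = {
    "symptom": ["出现{X}", "伴有{X}", "仍有{X}", "自觉{X}明显", "以{X}为主"],
    "test": ["行{X}检查", "复查{X}", "{X}结果正常", "完善{X}后评估"],
    "diagnosis": ["诊断为{X}", "考虑{X}", "明确诊断{X}"],
    "treatment": ["给予{X}", "予{X}抗感染", "继续{X}巩固"],
    "body_part": ["{X}未见异常", "{X}稍肿大", "查见{X}对称", "{X}无压痛"],
}

#: Entity-free clauses mixed in between entity clauses.
FILLER_CLAUSES = [
    "起病急",
    "病程短",
    "精神可",
    "饮食睡眠可",
    "体温38℃",
    "心率102次/分",
    "血压120/80mmHg",
    "病情平稳",
    "无明显诱因",
    "一般情况可",
    "大小便正常",
    "随访3天",
]

#: Multi-character template words with POS tags, for the built-in segmenter.
TEMPLATE_WORD_POS: list[tuple[str, str]] = [
    ("出现", "v"), ("伴有", "v"), ("仍有", "v"), ("自觉", "v"), ("明显", "a"),
    ("为主", "v"), ("检查", "vn"), ("复查", "v"), ("结果", "n"), ("正常", "a"),
    ("完善", "v"), ("评估", "vn"), ("诊断", "vn"), ("考虑", "v"), ("明确", "v"),
    ("给予", "v"), ("抗感染", "vn"), ("继续", "v"), ("巩固", "v"), ("未见", "v"),
    ("异常", "a"), ("肿大", "a"), ("查见", "v"), ("对称", "a"), ("压痛", "n"),
    ("起病", "v"), ("病程", "n"), ("精神", "n"), ("饮食", "n"), ("睡眠", "n"),
    ("体温", "n"), ("心率", "n"), ("血压", "n"), ("病情", "n"), ("平稳", "a"),
    ("诱因", "n"), ("一般", "a"), ("情况", "n"), ("大小便", "n"), ("随访", "v"),
]

_PUNCT = "，。、：；1234（）"


def _template_characters() -> set[str]:
    chars: set[str] = set(_PUNCT)
    for templates in TEMPLATES.values():
        for t in templates:
            chars |= set(t.replace("{X}", ""))
    for clause in FILLER_CLAUSES:
        chars |= set(clause)
    for word, _ in TEMPLATE_WORD_POS:
        chars |= set(word)
    return chars


def character_pool(size: int = 500) -> list[str]:
    """A deterministic pool of CJK code points excluding every template character."""
    forbidden = _template_characters()
    pool: list[str] = []
    cp = 0x4E00
    while len(pool) < size and cp < 0x9FFF:
        ch = chr(cp)
        if ch not in forbidden:
            pool.append(ch)
        cp += 1
    return pool


def generate_lexicons(
    seed: int,
    sizes: dict[str, int] | int = 50,
    heldout_fraction: float = 0.2,
    pool_size: int = 500,
) -> tuple[dict[str, list[str]], dict[str, list[str]]]:
    """Generate (train, held_out) category lexicons of unique 2-6-character terms.

    Each category draws from its own slice of the character pool, so terms —
    and even characters — are disjoint across categories by construction.
    """
    if isinstance(sizes, int):
        sizes = {cat: sizes for cat in CATEGORIES}
    for cat, n in sizes.items():
        if n < 1:
            raise ValueError(f"lexicon size for {cat!r} must be >= 1")
    rng = np.random.default_rng(seed)
    pool = character_pool(pool_size)
    rng.shuffle(pool)
    per_cat = len(pool) // len(CATEGORIES)
    train: dict[str, list[str]] = {}
    heldout: dict[str, list[str]] = {}
    for k, cat in enumerate(CATEGORIES):
        chars = pool[k * per_cat : (k + 1) * per_cat]
        terms: set[str] = set()
        attempts = 0
        while len(terms) < sizes[cat] and attempts < 100 * sizes[cat]:
            length = int(rng.integers(2, 7))
            terms.add("".join(rng.choice(chars, size=length)))
            attempts += 1
        ordered = sorted(terms)
        rng.shuffle(ordered)
        n_held = int(round(heldout_fraction * len(ordered)))
        heldout[cat] = sorted(ordered[:n_held])
        train[cat] = sorted(ordered[n_held:])
    return train, heldout


@dataclass
class GeneratorConfig:
    """Configuration of the synthetic corpus generator; the seed is mandatory."""

    seed: int
    n_documents: int = 100
    category_mix: dict[str, float] = field(default_factory=lambda: dict(DEFAULT_CATEGORY_MIX))
    lexicons: dict[str, list[str]] | None = None  # generated from the seed when None
    sentences_per_section: tuple[int, int] = (2, 4)
    clauses_per_sentence: tuple[int, int] = (1, 3)
    p_entity_clause: float = 0.7
    ambiguity: float = 0.0  # probability a slot draws from the shared ambiguous list
    n_ambiguous_terms: int = 5

    def __post_init__(self) -> None:
        if set(self.category_mix) != set(CATEGORIES):
            raise ValueError(f"category_mix must cover exactly {CATEGORIES}")
        total = sum(self.category_mix.values())
        if not np.isclose(total, 1.0, atol=1e-9):
            raise ValueError(f"category proportions sum to {total}, expected 1")
        if any(v < 0 for v in self.category_mix.values()):
            raise ValueError("category proportions must be non-negative")


def generate_corpus(config: GeneratorConfig) -> list[AnnotatedDocument]:
    """Generate annotated documents deterministically from the config seed."""
    rng = np.random.default_rng(config.seed)
    lexicons = config.lexicons
    if lexicons is None:
        lexicons, _ = generate_lexicons(config.seed)
    for cat in CATEGORIES:
        if not lexicons.get(cat):
            raise ValueError(f"empty lexicon for category {cat!r}")

    ambiguous: list[tuple[str, tuple[str, str]]] = []
    if config.ambiguity > 0.0:
        # Reuse symptom-pool surface forms under both symptom and diagnosis,
        # the classic context-dependent pair in clinical annotation.
        donors = lexicons["symptom"][: config.n_ambiguous_terms]
        ambiguous = [(term, ("symptom", "diagnosis")) for term in donors]

    mix_cats = list(config.category_mix)
    mix_probs = np.array([config.category_mix[c] for c in mix_cats])
    docs: list[AnnotatedDocument] = []
    for d in range(config.n_documents):
        parts: list[str] = []
        offset = 0
        entities: set[EntityMention] = set()

        def emit(s: str) -> None:
            nonlocal offset
            parts.append(s)
            offset += len(s)

        for section in range(1, 5):
            emit(f"{section}、")
            n_sent = int(rng.integers(config.sentences_per_section[0],
                                      config.sentences_per_section[1] + 1))
            for _ in range(n_sent):
                n_clause = int(rng.integers(config.clauses_per_sentence[0],
                                            config.clauses_per_sentence[1] + 1))
                for ci in range(n_clause):
                    if rng.random() < config.p_entity_clause:
                        cat = mix_cats[int(rng.choice(len(mix_cats), p=mix_probs))]
                        term = None
                        if ambiguous and cat in ("symptom", "diagnosis") and rng.random() < config.ambiguity:
                            term = ambiguous[int(rng.integers(len(ambiguous)))][0]
                        if term is None:
                            lex = lexicons[cat]
                            term = lex[int(rng.integers(len(lex)))]
                        template = TEMPLATES[cat][int(rng.integers(len(TEMPLATES[cat])))]
                        before, after = template.split("{X}")
                        emit(before)
                        start = offset
                        emit(term)
                        entities.add(EntityMention(term, start, offset - 1, cat))
                        emit(after)
                    else:
                        emit(FILLER_CLAUSES[int(rng.integers(len(FILLER_CLAUSES)))])
                    emit("，" if ci < n_clause - 1 else "。")
        doc = AnnotatedDocument(f"synthetic-{config.seed}-{d:04d}", "".join(parts), entities)
        doc.validate()
        docs.append(doc)
    return docs


def full_lexicon_pairs(*lexicons: dict[str, list[str]]) -> list[tuple[str, str]]:
    """Flatten lexicons to (term, category) pairs, e.g. for dictionary building."""
    pairs: list[tuple[str, str]] = []
    for lex in lexicons:
        for cat in CATEGORIES:
            pairs.extend((term, cat) for term in lex.get(cat, []))
    return pairs


def segmentation_lexicon(*lexicons: dict[str, list[str]]) -> list[tuple[str, str]]:
    """A ``(word, pos)`` lexicon for the built-in segmenter: every entity term
    as a noun plus the fixed template vocabulary."""
    pairs = [(term, "n") for term, _ in full_lexicon_pairs(*lexicons)]
    pairs.extend(TEMPLATE_WORD_POS)
    return pairs
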