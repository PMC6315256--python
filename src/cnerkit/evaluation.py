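"""Strict entity-level evaluation, error partition, and cross-validation.

An output entity counts as correct only under strict equivalence: mention
string, start offset, end offset, and category must all equal a gold
entity's.  With S the system set and G the gold set,

    P = |S intersect G| / |S|
    R = |S intersect G| / |G|
    F1 = 2PR / (P + R)       (0 when P + R = 0)

Counts are micro-pooled across documents (summed, then divided), which is
the direct reading of the set-cardinality formulas.  Errors are partitioned
three ways at the entity level:

* **GT-P** — gold entities with no character overlap to any prediction
  (entirely missed);
* **P-GT** — predicted entities with no character overlap to any gold
  entity (spurious);
* **INTERSECT** — connected groups of non-identical gold/predicted entities
  whose character spans overlap (boundary or category disagreements).

Every errored entity belongs to exactly one class; exact matches are
excluded from the partition.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np

from cnerkit.corpus import AnnotatedDocument, CATEGORIES, EntityMention


@dataclass
class CategoryScore:
    precision: float
    recall: float
    f1: float
    n_system: int
    n_gold: int
    n_correct: int


@dataclass
class IntersectGroup:
    """One connected component of overlapping, non-identical entities."""

    doc_id: str
    gold: list[EntityMention]
    predicted: list[EntityMention]


@dataclass
class ErrorPartition:
    gt_p: list[tuple[str, EntityMention]] = field(default_factory=list)
    p_gt: list[tuple[str, EntityMention]] = field(default_factory=list)
    intersect: list[IntersectGroup] = field(default_factory=list)

    @property
    def counts(self) -> dict[str, int]:
        return {
            "GT-P": len(self.gt_p),
            "P-GT": len(self.p_gt),
            "INTERSECT": len(self.intersect),
        }


@dataclass
class EvalReport:
    per_category: dict[str, CategoryScore]
    overall: CategoryScore
    errors: ErrorPartition

    def summary(self) -> str:
        """Human-readable table of per-category and overall scores."""
        lines = [f"{'category':<12}{'P':>8}{'R':>8}{'F1':>8}{'|S|':>7}{'|G|':>7}{'|S∩G|':>7}"]
        for cat, s in {**self.per_category, "overall": self.overall}.items():
            lines.append(
                f"{cat:<12}{s.precision:>8.4f}{s.recall:>8.4f}{s.f1:>8.4f}"
                f"{s.n_system:>7}{s.n_gold:>7}{s.n_correct:>7}"
            )
        c = self.errors.counts
        lines.append(
            f"errors: GT-P={c['GT-P']}  P-GT={c['P-GT']}  INTERSECT={c['INTERSECT']}"
        )
        return "\n".join(lines)


def strict_equal(o: EntityMention, g: EntityMention) -> bool:
    """True iff mention, pos_b, pos_e, and category all coincide."""
    return (
        o.mention == g.mention
        and o.pos_b == g.pos_b
        and o.pos_e == g.pos_e
        and o.category == g.category
    )


def _prf(n_correct: int, n_system: int, n_gold: int) -> CategoryScore:
    p = n_correct / n_system if n_system else 0.0
    r = n_correct / n_gold if n_gold else 0.0
    f1 = 2 * p * r / (p + r) if p + r > 0 else 0.0
    return CategoryScore(p, r, f1, n_system, n_gold, n_correct)


def evaluate(
    pred: Mapping[str, set[EntityMention]],
    gold: Mapping[str, set[EntityMention]],
) -> EvalReport:
    """Score per-document prediction sets against gold sets.

    Both mappings must cover the same document ids.  Per-category scores
    restrict the system and gold sets to that category; since EntityMention
    is hashable with exactly the four strict-equivalence fields, set
    intersection implements strict matching directly.
    """
    if set(pred) != set(gold):
        missing = set(gold) ^ set(pred)
        raise ValueError(f"document ids differ between prediction and gold: {sorted(missing)}")
    n_correct = {cat: 0 for cat in CATEGORIES}
    n_system = {cat: 0 for cat in CATEGORIES}
    n_gold = {cat: 0 for cat in CATEGORIES}
    errors = ErrorPartition()
    for doc_id in sorted(gold):
        s, g = pred[doc_id], gold[doc_id]
        for cat in CATEGORIES:
            s_cat = {e for e in s if e.category == cat}
            g_cat = {e for e in g if e.category == cat}
            n_system[cat] += len(s_cat)
            n_gold[cat] += len(g_cat)
            n_correct[cat] += len(s_cat & g_cat)
        part = classify_errors(s, g, doc_id=doc_id)
        errors.gt_p.extend(part.gt_p)
        errors.p_gt.extend(part.p_gt)
        errors.intersect.extend(part.intersect)
    per_category = {cat: _prf(n_correct[cat], n_system[cat], n_gold[cat]) for cat in CATEGORIES}
    overall = _prf(sum(n_correct.values()), sum(n_system.values()), sum(n_gold.values()))
    return EvalReport(per_category, overall, errors)


def classify_errors(
    pred: set[EntityMention],
    gold: set[EntityMention],
    doc_id: str = "",
) -> ErrorPartition:
    """Partition one document's errors into GT-P, P-GT, and INTERSECT.

    Exact matches are removed first.  Remaining entities with no character
    overlap to the other side are GT-P (gold) or P-GT (predicted); the rest
    form INTERSECT groups — connected components of the span-overlap graph —
    so an entity overlapping several counterparts is still counted once.
    """
    matched = pred & gold
    g_rest = sorted(gold - matched, key=EntityMention.sort_key)
    p_rest = sorted(pred - matched, key=EntityMention.sort_key)
    overlap_g: dict[EntityMention, list[EntityMention]] = {g: [] for g in g_rest}
    overlap_p: dict[EntityMention, list[EntityMention]] = {p: [] for p in p_rest}
    for g in g_rest:
        for p in p_rest:
            if g.overlaps(p):
                overlap_g[g].append(p)
                overlap_p[p].append(g)
    part = ErrorPartition()
    part.gt_p = [(doc_id, g) for g in g_rest if not overlap_g[g]]
    part.p_gt = [(doc_id, p) for p in p_rest if not overlap_p[p]]

    # connected components over the remaining (overlapping) entities
    seen: set[EntityMention] = set()
    for g in g_rest:
        if g in seen or not overlap_g[g]:
            continue
        comp_g: list[EntityMention] = []
        comp_p: list[EntityMention] = []
        stack: list[tuple[str, EntityMention]] = [("g", g)]
        while stack:
            side, ent = stack.pop()
            if ent in seen:
                continue
            seen.add(ent)
            if side == "g":
                comp_g.append(ent)
                stack.extend(("p", p) for p in overlap_g[ent])
            else:
                comp_p.append(ent)
                stack.extend(("g", gg) for gg in overlap_p[ent])
        part.intersect.append(
            IntersectGroup(
                doc_id,
                sorted(comp_g, key=EntityMention.sort_key),
                sorted(comp_p, key=EntityMention.sort_key),
            )
        )
    return part


def cross_validate(
    corpus: Sequence[AnnotatedDocument],
    k: int,
    trainer: Callable[[list[AnnotatedDocument]], Callable[[AnnotatedDocument], set[EntityMention]]],
    seed: int = 0,
) -> dict:
    """k-fold cross-validation over documents.

    The corpus is shuffled once with the given seed and cut into k
    contiguous folds; each fold is held out in turn while ``trainer`` fits
    on the remainder and returns a per-document predictor.  Returns the
    per-fold strict F1 scores, their mean and standard deviation, and the
    fold assignment.
    """
    if k < 2:
        raise ValueError(f"k must be at least 2, got {k}")
    if len(corpus) < k:
        raise ValueError(f"corpus of {len(corpus)} documents is smaller than k={k}")
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(corpus))
    bounds = np.linspace(0, len(corpus), k + 1).astype(int)
    folds = [order[bounds[i] : bounds[i + 1]].tolist() for i in range(k)]
    fold_f1: list[float] = []
    fold_reports: list[EvalReport] = []
    for held_out in folds:
        held_set = set(held_out)
        train_docs = [corpus[i] for i in order if i not in held_set]
        predictor = trainer(train_docs)
        pred = {corpus[i].doc_id: predictor(corpus[i]) for i in held_out}
        gold = {corpus[i].doc_id: set(corpus[i].entities) for i in held_out}
        report = evaluate(pred, gold)
        fold_reports.append(report)
        fold_f1.append(report.overall.f1)
    arr = np.array(fold_f1)
    return {
        "fold_f1": fold_f1,
        "mean_f1": float(arr.mean()),
        "sd_f1": float(arr.std(ddof=1)) if k > 1 else 0.0,
        "folds": folds,
        "reports": fold_reports,
    }
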