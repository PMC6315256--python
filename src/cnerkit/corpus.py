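"""Data model for offset-annotated clinical documents and the BIO codec.

Conventions (matching the CCKS-style gold standard):

* Offsets are 0-based and inclusive on both ends, counted in Unicode code
  points.  Every character — CJK, punctuation, digit, Latin letter — occupies
  exactly one position; there is no tokenization at the offset level.
* An entity mention must equal the document substring ``text[pos_b:pos_e+1]``.
* The tag scheme over the five clinical categories has 11 labels: a B- and an
  I- label per category plus O, with O fixed at index 0.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

#: Characters that terminate a sentence.  The gold format never defines
#: sentence boundaries; this set matches CJK clinical prose plus newline.
SENTENCE_TERMINATORS = "。！？；\n"  # 。！？； and newline

CATEGORIES = ("symptom", "test", "diagnosis", "treatment", "body_part")

#: Short label suffix used in B-/I- tags for each category.
_LABEL_SUFFIX = {
    "symptom": "symptom",
    "test": "test",
    "diagnosis": "diagnosis",
    "treatment": "treatment",
    "body_part": "body",
}
_SUFFIX_CATEGORY = {v: k for k, v in _LABEL_SUFFIX.items()}


class CorpusError(ValueError):
    """Raised on malformed annotations, offsets, or label sequences."""


@dataclass(frozen=True)
class EntityMention:
    """A single clinical entity anchored by inclusive character offsets."""

    mention: str
    pos_b: int
    pos_e: int
    category: str

    def __post_init__(self) -> None:
        if self.pos_b > self.pos_e:
            raise CorpusError(
                f"pos_b {self.pos_b} > pos_e {self.pos_e} for mention {self.mention!r}"
            )
        if len(self.mention) != self.pos_e - self.pos_b + 1:
            raise CorpusError(
                f"mention {self.mention!r} has length {len(self.mention)} but spans "
                f"[{self.pos_b}, {self.pos_e}] ({self.pos_e - self.pos_b + 1} characters)"
            )
        if self.category not in CATEGORIES:
            raise CorpusError(f"unknown category {self.category!r}")

    @property
    def span(self) -> tuple[int, int]:
        return (self.pos_b, self.pos_e)

    def overlaps(self, other: "EntityMention") -> bool:
        return self.pos_b <= other.pos_e and other.pos_b <= self.pos_e

    def sort_key(self) -> tuple[int, int, str]:
        return (self.pos_b, self.pos_e, self.category)


@dataclass
class AnnotatedDocument:
    """A clinical document plus its set of gold entity mentions."""

    doc_id: str
    text: str
    entities: set[EntityMention] = field(default_factory=set)

    def validate(self) -> None:
        """Check offset bounds, substring identity, and non-overlap."""
        n = len(self.text)
        ordered = sorted(self.entities, key=EntityMention.sort_key)
        for ent in ordered:
            if ent.pos_b < 0 or ent.pos_e >= n:
                raise CorpusError(
                    f"{self.doc_id}: entity {ent.mention!r} offsets "
                    f"[{ent.pos_b}, {ent.pos_e}] outside text of length {n}"
                )
            actual = self.text[ent.pos_b : ent.pos_e + 1]
            if actual != ent.mention:
                raise CorpusError(
                    f"{self.doc_id}: mention {ent.mention!r} != text substring "
                    f"{actual!r} at [{ent.pos_b}, {ent.pos_e}]"
                )
        for a, b in zip(ordered, ordered[1:]):
            if a.overlaps(b):
                raise CorpusError(
                    f"{self.doc_id}: overlapping entities {a.mention!r} "
                    f"[{a.pos_b},{a.pos_e}] and {b.mention!r} [{b.pos_b},{b.pos_e}]"
                )


class TagScheme:
    """The 11-label BIO inventory over the five clinical categories.

    Label order is fixed as ``[O, B-symptom, I-symptom, B-test, I-test,
    B-diagnosis, I-diagnosis, B-treatment, I-treatment, B-body, I-body]``
    for reproducible indexing; O is always index 0.
    """

    def __init__(self, categories: Sequence[str] = CATEGORIES) -> None:
        self.categories = tuple(categories)
        labels = ["O"]
        for cat in self.categories:
            suffix = _LABEL_SUFFIX.get(cat, cat)
            labels.append(f"B-{suffix}")
            labels.append(f"I-{suffix}")
        self.labels = tuple(labels)
        self.label_to_index = {lab: i for i, lab in enumerate(self.labels)}

    @property
    def n_labels(self) -> int:
        return len(self.labels)

    def index(self, label: str) -> int:
        try:
            return self.label_to_index[label]
        except KeyError:
            raise CorpusError(f"unknown label {label!r}") from None

    def b_label(self, category: str) -> str:
        return f"B-{_LABEL_SUFFIX.get(category, category)}"

    def i_label(self, category: str) -> str:
        return f"I-{_LABEL_SUFFIX.get(category, category)}"

    @staticmethod
    def parse_label(label: str) -> tuple[str, str | None]:
        """Split a label into (prefix, category); O parses to ('O', None)."""
        if label == "O":
            return "O", None
        if len(label) > 2 and label[1] == "-" and label[0] in "BI":
            suffix = label[2:]
            if suffix in _SUFFIX_CATEGORY:
                return label[0], _SUFFIX_CATEGORY[suffix]
        raise CorpusError(f"unknown label {label!r}")


@dataclass
class TaggedSentence:
    """A sentence as parallel character and BIO label sequences.

    ``doc_offset`` anchors the first character in the source document so
    entity offsets can be reconstructed at the document level.
    """

    chars: str
    labels: list[str]
    doc_offset: int = 0
    doc_id: str = ""

    def __post_init__(self) -> None:
        if len(self.chars) != len(self.labels):
            raise CorpusError(
                f"{len(self.chars)} characters but {len(self.labels)} labels"
            )

    def __len__(self) -> int:
        return len(self.chars)


def split_sentences(text: str) -> list[tuple[str, int]]:
    """Split text into (sentence, start_offset) pairs.

    Each sentence ends at an ending punctuation mark (。！？；, or newline) or
    at end-of-text; concatenating the sentences reconstructs the text exactly.
    """
    sentences: list[tuple[str, int]] = []
    start = 0
    for i, ch in enumerate(text):
        if ch in SENTENCE_TERMINATORS:
            sentences.append((text[start : i + 1], start))
            start = i + 1
    if start < len(text):
        sentences.append((text[start:], start))
    return sentences


def entities_to_bio(doc: AnnotatedDocument, scheme: TagScheme | None = None) -> list[TaggedSentence]:
    """Encode a document's entities as per-sentence BIO label sequences.

    The character at ``pos_b`` of each entity receives ``B-category`` and
    characters ``pos_b+1 .. pos_e`` receive ``I-category``; all other
    characters are O.  Entities crossing a sentence boundary are rejected.
    """
    scheme = scheme or TagScheme()
    doc.validate()
    sentences = split_sentences(doc.text)
    tagged: list[TaggedSentence] = []
    ordered = sorted(doc.entities, key=EntityMention.sort_key)
    idx = 0
    for sent, start in sentences:
        end = start + len(sent) - 1  # inclusive
        labels = ["O"] * len(sent)
        while idx < len(ordered) and ordered[idx].pos_b <= end:
            ent = ordered[idx]
            if ent.pos_e > end:
                raise CorpusError(
                    f"{doc.doc_id}: entity {ent.mention!r} [{ent.pos_b},{ent.pos_e}] "
                    f"crosses the sentence boundary at offset {end}"
                )
            labels[ent.pos_b - start] = scheme.b_label(ent.category)
            for k in range(ent.pos_b + 1, ent.pos_e + 1):
                labels[k - start] = scheme.i_label(ent.category)
            idx += 1
        tagged.append(TaggedSentence(sent, labels, doc_offset=start, doc_id=doc.doc_id))
    return tagged


def bio_to_entities(sent: TaggedSentence, scheme: TagScheme | None = None) -> set[EntityMention]:
    """Decode BIO labels back into offset-anchored entity mentions.

    Maximal ``B-x (I-x)*`` runs become mentions with document-level offsets.
    A dangling ``I-x`` (not preceded by B-x or I-x of the same category) is
    repaired to ``B-x`` — the standard recall-preserving CoNLL convention —
    so every label sequence decodes to a legal mention set.
    """
    scheme = scheme or TagScheme()
    entities: set[EntityMention] = set()
    run_start: int | None = None
    run_cat: str | None = None

    def flush(end_idx: int) -> None:
        nonlocal run_start, run_cat
        if run_start is not None and run_cat is not None:
            b = sent.doc_offset + run_start
            e = sent.doc_offset + end_idx
            entities.add(
                EntityMention(sent.chars[run_start : end_idx + 1], b, e, run_cat)
            )
        run_start = run_cat = None

    for i, label in enumerate(sent.labels):
        prefix, cat = TagScheme.parse_label(label)
        if prefix == "O":
            flush(i - 1)
        elif prefix == "B":
            flush(i - 1)
            run_start, run_cat = i, cat
        else:  # I
            if run_cat == cat:
                continue  # extend current run
            flush(i - 1)  # dangling I: repair to B
            run_start, run_cat = i, cat
    flush(len(sent.labels) - 1)
    return entities


# ---------------------------------------------------------------------------
# Offset-TSV (CCKS-style) annotation files
# ---------------------------------------------------------------------------

def read_annotations(text_file: str | Path, tsv_file: str | Path, doc_id: str | None = None) -> AnnotatedDocument:
    """Read a document from a plain-text file plus an offset TSV.

    TSV columns are ``mention pos_b pos_e category`` (tab separated).
    The mention-equals-substring invariant is validated; mismatches are
    reported with the offending offsets and the actual substring.
    """
    text_file, tsv_file = Path(text_file), Path(tsv_file)
    text = text_file.read_text(encoding="utf-8")
    entities: set[EntityMention] = set()
    for lineno, line in enumerate(tsv_file.read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 4:
            raise CorpusError(f"{tsv_file}:{lineno}: expected 4 tab-separated columns, got {len(parts)}")
        mention, b_str, e_str, category = parts
        try:
            pos_b, pos_e = int(b_str), int(e_str)
        except ValueError:
            raise CorpusError(f"{tsv_file}:{lineno}: non-integer offsets {b_str!r}, {e_str!r}") from None
        try:
            ent = EntityMention(mention, pos_b, pos_e, category)
        except CorpusError as exc:
            raise CorpusError(f"{tsv_file}:{lineno}: {exc}") from None
        actual = text[pos_b : pos_e + 1]
        if actual != mention:
            raise CorpusError(
                f"{tsv_file}:{lineno}: mention {mention!r} does not equal text "
                f"substring {actual!r} at [{pos_b}, {pos_e}]"
            )
        entities.add(ent)
    doc = AnnotatedDocument(doc_id or text_file.stem, text, entities)
    doc.validate()
    return doc


def write_annotations(doc: AnnotatedDocument) -> str:
    """Render a document's entities as CCKS-style TSV rows (sorted by offset)."""
    rows = [
        f"{e.mention}\t{e.pos_b}\t{e.pos_e}\t{e.category}"
        for e in sorted(doc.entities, key=EntityMention.sort_key)
    ]
    return "\n".join(rows) + ("\n" if rows else "")


# ---------------------------------------------------------------------------
# CoNLL two-column character/label files
# ---------------------------------------------------------------------------

def write_conll(sentences: Iterable[TaggedSentence]) -> str:
    """Render sentences as two-column ``char<TAB>label`` blocks separated by blank lines."""
    blocks = []
    for sent in sentences:
        blocks.append(
            "\n".join(f"{ch}\t{lab}" for ch, lab in zip(sent.chars, sent.labels))
        )
    return "\n\n".join(blocks) + ("\n" if blocks else "")


def read_conll(source: str | Path, scheme: TagScheme | None = None) -> list[TaggedSentence]:
    """Parse a CoNLL-style two-column file back into tagged sentences.

    Accepts a path or raw content.  Document offsets are assigned by
    concatenation order so that round-tripping a corpus written from a single
    document preserves relative positions.
    """
    scheme = scheme or TagScheme()
    if isinstance(source, Path) or (isinstance(source, str) and "\t" not in source and "\n" not in source and Path(source).exists()):
        content = Path(source).read_text(encoding="utf-8")
    else:
        content = str(source)
    sentences: list[TaggedSentence] = []
    chars: list[str] = []
    labels: list[str] = []
    offset = 0

    def flush() -> None:
        nonlocal chars, labels, offset
        if chars:
            sentences.append(TaggedSentence("".join(chars), labels, doc_offset=offset))
            offset += len(chars)
            chars, labels = [], []

    for lineno, line in enumerate(content.splitlines(), start=1):
        if not line.strip():
            flush()
            continue
        parts = line.split("\t")
        if len(parts) != 2 or len(parts[0]) != 1:
            raise CorpusError(f"line {lineno}: expected 'char<TAB>label', got {line!r}")
        scheme.index(parts[1])  # validates the label
        chars.append(parts[0])
        labels.append(parts[1])
    flush()
    return sentences
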