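"""Pluggable word segmentation with part-of-speech tags.

The feature extractor needs, for every character, the POS tag of the word
containing it and a BMES word-boundary tag.  Any callable mapping a sentence
to ``[(word, pos_tag), ...]`` whose words concatenate back to the sentence
satisfies the contract; the built-in implementation is a maximum-forward-
matching segmenter over a ``word -> pos`` lexicon, with unknown characters
falling out as single-character words tagged ``x``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Callable, Iterable

Segmenter = Callable[[str], list[tuple[str, str]]]

#: POS tag assigned to characters not covered by the lexicon.
UNKNOWN_POS = "x"


@dataclass
class LexiconSegmenter:
    """Greedy longest-match segmenter over a word lexicon with POS tags."""

    lexicon: dict[str, str] = field(default_factory=dict)
    max_len: int = 0

    @classmethod
    def from_pairs(cls, pairs: Iterable[tuple[str, str]]) -> "LexiconSegmenter":
        lex = {}
        for word, pos in pairs:
            if not word:
                raise ValueError("empty word in segmentation lexicon")
            lex.setdefault(word, pos)
        return cls(lex, max((len(w) for w in lex), default=0))

    @classmethod
    def from_file(cls, path: str | Path) -> "LexiconSegmenter":
        """Load a ``word<TAB>pos`` lexicon file (UTF-8, one entry per line)."""
        pairs = []
        for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
            if not line.strip():
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ValueError(f"{path}:{lineno}: expected 'word<TAB>pos'")
            pairs.append((parts[0], parts[1]))
        return cls.from_pairs(pairs)

    def __call__(self, sentence: str) -> list[tuple[str, str]]:
        tokens: list[tuple[str, str]] = []
        n = len(sentence)
        p = 0
        while p < n:
            for length in range(min(self.max_len, n - p), 1, -1):
                word = sentence[p : p + length]
                if word in self.lexicon:
                    tokens.append((word, self.lexicon[word]))
                    p += length
                    break
            else:
                ch = sentence[p]
                tokens.append((ch, self.lexicon.get(ch, UNKNOWN_POS)))
                p += 1
        return tokens


def character_segmenter(sentence: str) -> list[tuple[str, str]]:
    """Degenerate fallback: every character is its own word, POS unknown."""
    return [(ch, UNKNOWN_POS) for ch in sentence]
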