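"""Category-mapped term dictionary and the maximum-forward-matching baseline.

Maximum forward matching is the classic greedy dictionary recognizer for
Chinese text: scan left to right and, at each position, emit the longest
dictionary term that starts there, then resume after it.  Matching is exact
on code points — no width normalization — so emitted offsets stay aligned
with the raw text.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

from cnerkit.corpus import CATEGORIES, EntityMention

logger = logging.getLogger(__name__)


@dataclass
class TermDictionary:
    """Map from term string to clinical category, with the longest-term length cached."""

    entries: dict[str, str] = field(default_factory=dict)
    max_len: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __contains__(self, term: str) -> bool:
        return term in self.entries


def build_dictionary(sources: Iterable[tuple[str, str]]) -> TermDictionary:
    """Build a deduplicated dictionary from (term, category) pairs.

    A term seen under two different categories keeps the first category and
    logs a warning (first-source-wins).  Empty terms are rejected.
    """
    entries: dict[str, str] = {}
    for term, category in sources:
        if not term:
            raise ValueError("empty dictionary term")
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r} for term {term!r}")
        if term in entries:
            if entries[term] != category:
                logger.warning(
                    "term %r already mapped to %r; ignoring conflicting category %r",
                    term, entries[term], category,
                )
            continue
        entries[term] = category
    max_len = max((len(t) for t in entries), default=0)
    return TermDictionary(entries, max_len)


def load_dictionary(path: str | Path) -> TermDictionary:
    """Load a dictionary file: one ``term<TAB>category`` per line, UTF-8."""
    pairs = []
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), start=1):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != 2:
            raise ValueError(f"{path}:{lineno}: expected 'term<TAB>category', got {line!r}")
        pairs.append((parts[0], parts[1]))
    return build_dictionary(pairs)


def save_dictionary(dictionary: TermDictionary, path: str | Path) -> None:
    lines = [f"{t}\t{c}" for t, c in sorted(dictionary.entries.items())]
    Path(path).write_text("\n".join(lines) + ("\n" if lines else ""), encoding="utf-8")


def max_forward_match(text: str, dictionary: TermDictionary) -> set[EntityMention]:
    """Extract entities by maximum forward matching over the whole document.

    At position ``p`` the longest dictionary term starting at ``p`` is emitted
    with inclusive offsets ``[p, p+len-1]`` and the scan resumes at ``p+len``;
    if nothing matches the scan advances one character.  Emitted mentions
    never overlap.  Lookup probes term lengths from ``min(max_len,
    remaining)`` down to 1 against the hash map.
    """
    matches: set[EntityMention] = set()
    if not dictionary.entries:
        return matches
    n = len(text)
    p = 0
    while p < n:
        longest = min(dictionary.max_len, n - p)
        for length in range(longest, 0, -1):
            candidate = text[p : p + length]
            category = dictionary.entries.get(candidate)
            if category is not None:
                matches.add(EntityMention(candidate, p, p + length - 1, category))
                p += length
                break
        else:
            p += 1
    return matches
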