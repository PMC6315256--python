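"""Character-level feature extraction for the CRF tagger.

Four feature families are supported, mirroring classic CRF++ templates for
Chinese sequence labeling:

* **BOC** (bag of characters): character unigrams over a ±2 window
  (``C-2 .. C+2``) plus the two adjacent bigrams ``C-1C0`` and ``C0C+1``;
* **POS**: the part-of-speech tag of the containing word, projected onto
  each character, over the same window (``POS-2 .. POS+2``);
* **CT** (character type): one of W (common character), D (digit),
  L (Latin letter), S (ending punctuation), P (paired/symmetrical
  punctuation), over the window (``CT-2 .. CT+2``);
* **POCIS** (position of character in sentence): FIRST/LAST for the boundary
  characters, else the quartile bucket of ``index / length``.

Features are rendered as plain ``template_id=value`` strings; positions
outside the sentence yield the boundary sentinels ``<S>`` / ``<E>``.
"""

from __future__ import annotations

from dataclasses import dataclass

from cnerkit.segmenter import Segmenter

FAMILIES = ("boc", "pos", "ct", "pocis")

_SENT_START = "<S>"
_SENT_END = "<E>"

# Character-type inventories.  Digits and Latin letters in both ASCII and
# full-width forms; ending punctuation covers CJK and ASCII sentence enders;
# paired punctuation covers brackets, quotes, and pause/clause separators.
_DIGITS = set("0123456789０１２３４５６７８９")
_LETTERS = set(
    "abcdefghijklmnopqrstuvwxyzABCDEFGHIJKLMNOPQRSTUVWXYZ"
    "ａｂｃｄｅｆｇｈｉｊｋｌｍｎｏｐｑｒｓｔｕｖｗｘｙｚ"
    "ＡＢＣＤＥＦＧＨＩＪＫＬＭＮＯＰＱＲＳＴＵＶＷＸＹＺ"
)
_ENDING_PUNCT = set("。！？；.!?;")
_PAIRED_PUNCT = set("（）()《》【】[]“”‘’、，,：:")


def char_type(ch: str) -> str:
    """Classify a single character as W, D, L, S, or P (a total function)."""
    if len(ch) != 1:
        raise ValueError(f"char_type expects a single character, got {ch!r}")
    if ch in _DIGITS:
        return "D"
    if ch in _LETTERS:
        return "L"
    if ch in _ENDING_PUNCT:
        return "S"
    if ch in _PAIRED_PUNCT:
        return "P"
    return "W"


def project_pos(tokens: list[tuple[str, str]]) -> list[str]:
    """Project word-level POS tags onto characters.

    Each character receives the tag of the word containing it, so the output
    length equals the concatenated sentence length.
    """
    tags: list[str] = []
    for word, pos in tokens:
        tags.extend([pos] * len(word))
    return tags


def seg_bmes(tokens: list[str]) -> list[str]:
    """Encode word boundaries as per-character BMES tags.

    A single-character word is S; a k-character word is B M^(k-2) E.
    """
    tags: list[str] = []
    for word in tokens:
        if not word:
            raise ValueError("empty word in segmentation")
        if len(word) == 1:
            tags.append("S")
        else:
            tags.append("B")
            tags.extend(["M"] * (len(word) - 2))
            tags.append("E")
    return tags


def pocis(index: int, length: int) -> str:
    """Bucket a character position: FIRST/LAST at the boundaries, else the
    quartile of ``index / length`` (Q1..Q4)."""
    if not 0 <= index < length:
        raise ValueError(f"index {index} out of range for sentence length {length}")
    if index == 0:
        return "FIRST"
    if index == length - 1:
        return "LAST"
    q = index / length
    if q < 0.25:
        return "Q1"
    if q < 0.5:
        return "Q2"
    if q < 0.75:
        return "Q3"
    return "Q4"


@dataclass(frozen=True)
class FeatureConfig:
    """Which feature families are active, plus the context window size.

    ``window`` is the total window (default 5: the two preceding characters,
    the current character, and the two following characters).  ``bigrams``
    toggles the two adjacent BOC bigram templates.
    """

    families: tuple[str, ...] = FAMILIES
    window: int = 5
    bigrams: bool = True

    def __post_init__(self) -> None:
        for fam in self.families:
            if fam not in FAMILIES:
                raise ValueError(f"unknown feature family {fam!r}; expected one of {FAMILIES}")
        if self.window < 1 or self.window % 2 == 0:
            raise ValueError(f"window must be a positive odd number, got {self.window}")

    @property
    def half(self) -> int:
        return self.window // 2


def _window_value(values: str | list[str], i: int) -> str:
    if i < 0:
        return _SENT_START
    if i >= len(values):
        return _SENT_END
    return values[i]


def extract_features(
    chars: str,
    i: int,
    config: FeatureConfig = FeatureConfig(),
    pos_tags: list[str] | None = None,
) -> list[str]:
    """Extract the feature strings for position ``i`` of a sentence.

    ``pos_tags`` is the per-character projected POS sequence; required when
    the ``pos`` family is active.  Extraction is deterministic and depends
    only on the window contents, the POS annotations, and sentence length.
    """
    if not 0 <= i < len(chars):
        raise ValueError(f"position {i} out of range for sentence of length {len(chars)}")
    feats: list[str] = []
    h = config.half
    if "boc" in config.families:
        for d in range(-h, h + 1):
            feats.append(f"C{d:+d}={_window_value(chars, i + d)}")
        if config.bigrams:
            feats.append(f"C-1C0={_window_value(chars, i - 1)}{chars[i]}")
            feats.append(f"C0C+1={chars[i]}{_window_value(chars, i + 1)}")
    if "pos" in config.families:
        if pos_tags is None:
            raise ValueError("pos family requires pos_tags")
        if len(pos_tags) != len(chars):
            raise ValueError(
                f"pos_tags length {len(pos_tags)} != sentence length {len(chars)}"
            )
        for d in range(-h, h + 1):
            feats.append(f"POS{d:+d}={_window_value(pos_tags, i + d)}")
    if "ct" in config.families:
        for d in range(-h, h + 1):
            j = i + d
            value = char_type(chars[j]) if 0 <= j < len(chars) else _window_value(chars, j)
            feats.append(f"CT{d:+d}={value}")
    if "pocis" in config.families:
        feats.append(f"POCIS={pocis(i, len(chars))}")
    return feats


def sentence_features(
    chars: str,
    config: FeatureConfig = FeatureConfig(),
    segmenter: Segmenter | None = None,
) -> list[list[str]]:
    """Extract features for every position of a sentence.

    Runs the segmenter once (when the POS family is active) and reuses the
    projected tags across positions.
    """
    pos_tags: list[str] | None = None
    if "pos" in config.families:
        if segmenter is None:
            raise ValueError("pos family requires a segmenter")
        tokens = segmenter(chars)
        if "".join(w for w, _ in tokens) != chars:
            raise ValueError("segmenter output does not reconstruct the sentence")
        pos_tags = project_pos(tokens)
    return [extract_features(chars, i, config, pos_tags) for i in range(len(chars))]
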