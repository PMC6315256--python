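"""A published CCKS-2017-style worked example: one pediatric progress-note
excerpt with its 16 gold entity annotations.

This is the standard demonstration record for the CCKS clinical NER task
format: a short bronchopneumonia progress note whose gold standard annotates
every symptom, test, diagnosis, treatment, and body-part mention with
0-based inclusive character offsets.  It is used throughout the test suite
and examples as a fixed, hand-checkable input.
"""

from __future__ import annotations

from cnerkit.corpus import AnnotatedDocument, EntityMention

EXAMPLE_TEXT = (
    "1、患儿为4岁儿童，起病急，病程短。2、以咳嗽，发热为主症。3、查体：咽部稍充血，"
    "双扁桃体稍肿大。双肺呼吸音粗，可闻及中小水泡音，结合胸片故诊断为：支气管肺炎。"
    "给予静点头孢哌酮、炎琥宁联合抗感染、雾化吸入布地奈德、沙丁胺醇减轻气道高反应"
)

#: Gold standard: (mention, pos_b, pos_e, category), 0-based inclusive offsets.
EXAMPLE_GOLD_ROWS: list[tuple[str, int, int, str]] = [
    ("咳嗽", 21, 22, "symptom"),
    ("发热", 24, 25, "symptom"),
    ("查体", 32, 33, "test"),
    ("咽部", 35, 36, "body_part"),
    ("充血", 38, 39, "symptom"),
    ("双扁桃体", 41, 44, "body_part"),
    ("肿大", 46, 47, "symptom"),
    ("双肺", 49, 50, "body_part"),
    ("呼吸音", 51, 53, "test"),
    ("胸片", 67, 68, "test"),
    ("支气管肺炎", 74, 78, "diagnosis"),
    ("头孢哌酮", 84, 87, "treatment"),
    ("炎琥宁", 89, 91, "treatment"),
    ("布地奈德", 102, 105, "treatment"),
    ("沙丁胺醇", 107, 110, "treatment"),
    ("气道", 113, 114, "body_part"),
]


def example_document() -> AnnotatedDocument:
    """The worked example as a validated :class:`AnnotatedDocument`."""
    doc = AnnotatedDocument(
        "worked_example",
        EXAMPLE_TEXT,
        {EntityMention(m, b, e, c) for m, b, e, c in EXAMPLE_GOLD_ROWS},
    )
    doc.validate()
    return doc


def example_dictionary_pairs() -> list[tuple[str, str]]:
    """The 16 (term, category) pairs of the worked example's gold standard."""
    return [(m, c) for m, _, _, c in EXAMPLE_GOLD_ROWS]
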