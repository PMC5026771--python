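"""Shared fixtures: hand-built sentences and tiny corpora.

The central fixture reproduces the printed fragment of the motivating
sentence — "... express either decreased or increased numbers of VDR" —
with its basic Stanford dependency analysis, which anchors the distance,
n-gram and dependency-path feature checks.
"""

from __future__ import annotations

import pytest

from iem.standoff import (
    DependencyGraph,
    Document,
    Sentence,
    Token,
    attach_sentences,
    read_standoff_document,
)


def make_sentence(
    words: list[tuple[str, str, str]],
    deps: set[tuple[int, int, str]],
    proteins: dict[int, str] | None = None,
    index: int = 0,
    offset: int = 0,
) -> Sentence:
    """Build a Sentence from (surface, baseform, POS) triples."""
    tokens = []
    pos_cursor = offset
    for i, (surface, base, pos) in enumerate(words):
        tokens.append(
            Token(
                i,
                surface,
                base,
                pos,
                pos_cursor,
                pos_cursor + len(surface),
                (proteins or {}).get(i),
            )
        )
        pos_cursor += len(surface) + 1
    return Sentence(tokens, DependencyGraph(frozenset(deps)), index=index)


@pytest.fixture
def sentence1() -> Sentence:
    """Fragment "express either decreased or increased numbers of VDR".

    Dependencies follow the printed analysis: 'numbers' is the direct
    object of 'express' and 'decreased'/'increased' are its adjectival
    modifiers (the conjunction-inferred relation included).
    """
    words = [
        ("express", "express", "VBP"),
        ("either", "either", "CC"),
        ("decreased", "decrease", "VBN"),
        ("or", "or", "CC"),
        ("increased", "increase", "VBN"),
        ("numbers", "number", "NNS"),
        ("of", "of", "IN"),
        ("VDR", "vdr", "NN"),
    ]
    deps = {
        (0, 5, "dobj"),
        (5, 2, "amod"),
        (5, 4, "amod"),
        (2, 1, "cc"),
        (2, 3, "cc"),
        (5, 6, "prep"),
        (6, 7, "pobj"),
    }
    return make_sentence(words, deps, proteins={7: "T1"})


@pytest.fixture
def sentence5_tail() -> Sentence:
    """Tail of sentence (5): "... at relatively high levels , was also
    slightly augmented" — the comma is a punctuation token that must not
    count toward linear distances ('levels' to 'augmented' is four)."""
    words = [
        ("at", "at", "IN"),
        ("relatively", "relatively", "RB"),
        ("high", "high", "JJ"),
        ("levels", "level", "NNS"),
        (",", ",", ","),
        ("was", "be", "VBD"),
        ("also", "also", "RB"),
        ("slightly", "slightly", "RB"),
        ("augmented", "augment", "VBN"),
    ]
    deps = {
        (3, 2, "amod"),
        (0, 3, "pobj"),
        (8, 5, "auxpass"),
        (8, 6, "advmod"),
        (8, 7, "advmod"),
    }
    return make_sentence(words, deps)


def doc_from_strings(
    doc_id: str, txt: str, a1: str, a2: str, tok: str, dep: str
) -> Document:
    doc = read_standoff_document(doc_id, txt, a1, a2)
    attach_sentences(doc, tok, dep)
    return doc


@pytest.fixture
def nested_doc() -> Document:
    """One sentence, GE nested under PosReg: "TNF enhanced the expression of VDR ." """
    txt = "TNF enhanced the expression of VDR ."
    a1 = "T1\tProtein 0 3\tTNF\nT2\tProtein 31 34\tVDR\n"
    a2 = (
        "T10\tGene_expression 17 27\texpression\n"
        "T11\tPositive_regulation 4 12\tenhanced\n"
        "E1\tGene_expression:T10 Theme:T2\n"
        "E2\tPositive_regulation:T11 Theme:E1 Cause:T1\n"
    )
    tok = (
        "TNF\ttnf\tNN\nenhanced\tenhance\tVBD\nthe\tthe\tDT\n"
        "expression\texpression\tNN\nof\tof\tIN\nVDR\tvdr\tNN\n.\t.\t.\n"
    )
    dep = (
        "nsubj(enhanced-2, TNF-1)\ndet(expression-4, the-3)\n"
        "dobj(enhanced-2, expression-4)\nprep(expression-4, of-5)\n"
        "pobj(of-5, VDR-6)\n"
    )
    return doc_from_strings("D1", txt, a1, a2, tok, dep)


@pytest.fixture
def merged_loop_doc() -> Document:
    """GE/PR trigger-sharing loop: "VDR was overexpressed ." """
    txt = "VDR was overexpressed ."
    a1 = "T1\tProtein 0 3\tVDR\n"
    a2 = (
        "T10\tGene_expression 8 21\toverexpressed\n"
        "T11\tPositive_regulation 8 21\toverexpressed\n"
        "E1\tGene_expression:T10 Theme:T1\n"
        "E2\tPositive_regulation:T11 Theme:E1\n"
    )
    tok = "VDR\tvdr\tNN\nwas\tbe\tVBD\noverexpressed\toverexpress\tVBN\n.\t.\t.\n"
    dep = "nsubjpass(overexpressed-3, VDR-1)\nauxpass(overexpressed-3, was-2)\n"
    return doc_from_strings("D2", txt, a1, a2, tok, dep)
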