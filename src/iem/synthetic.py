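"""Synthetic desk-scale corpora for every pipeline stage.

Sentences are built from templates with deterministic template-derived
dependency trees and lexical analyses, so no parser is involved.  The
generator emulates the structural phenomena the method cares about:
protein mentions (single- and multi-word), single- and multi-word event
triggers of the nine event types, overlapping trigger vocabularies
(multi-label anchor words), nested event-taking events, GE/PR
trigger-sharing loops (merged events), and controllable trigger-span
inconsistency — the same semantic pattern annotated under the head-word
convention ("increased levels") or the modifier convention ("increased").

It does not attempt realistic biomedical language modeling; documents
are written through the standoff machinery, so generated corpora
round-trip through corpus I/O by construction.
"""

from __future__ import annotations

import random
from dataclasses import dataclass, field, replace
from typing import Callable, Sequence

from .ontology import (
    BINDING,
    CAUSE,
    GENE_EXPRESSION,
    LOCALIZATION,
    NEGATIVE_REGULATION,
    PHOSPHORYLATION,
    POSITIVE_REGULATION,
    PROTEIN_CATABOLISM,
    REGULATION,
    THEME,
    TRANSCRIPTION,
)
from .standoff import Document, attach_sentences, read_standoff_document, tokenize

DEFAULT_EVENT_FREQUENCIES: dict[str, float] = {
    GENE_EXPRESSION: 0.24,
    POSITIVE_REGULATION: 0.20,
    NEGATIVE_REGULATION: 0.12,
    REGULATION: 0.08,
    BINDING: 0.12,
    PHOSPHORYLATION: 0.08,
    TRANSCRIPTION: 0.06,
    LOCALIZATION: 0.06,
    PROTEIN_CATABOLISM: 0.04,
}

DEFAULT_PROTEIN_POOL: tuple[str, ...] = (
    "VDR",
    "STAT1",
    "IL-2",
    "TNF",
    "CD40",
    "p53",
    "c-jun",
    "E-selectin",
    "NF kappaB",
    "IFN-gamma",
)

DEFAULT_TRIGGER_VOCAB: dict[str, tuple[str, ...]] = {
    GENE_EXPRESSION: ("expressed", "expression", "production", "synthesis"),
    TRANSCRIPTION: ("expression", "transcription"),
    PHOSPHORYLATION: ("phosphorylation",),
    LOCALIZATION: ("secretion", "translocation"),
    PROTEIN_CATABOLISM: ("degradation",),
    BINDING: ("binds", "binding", "interaction"),
    POSITIVE_REGULATION: ("enhanced", "induced", "increased", "elevated", "overexpressed"),
    NEGATIVE_REGULATION: ("suppressed", "inhibited", "decreased", "reduced"),
    REGULATION: ("regulated", "modulated"),
}


@dataclass
class GeneratorConfig:
    """Conditions of the synthetic corpus.

    ``span_inconsistency_rate`` is the fraction of eligible multi-word
    triggers re-annotated under the modifier-word convention;
    ``nesting_probability`` controls event-taking events over nested GE
    events vs. direct protein THEMEs; ``merged_loop_probability`` the
    fraction of Positive Regulation sentences emitting the GE/PR
    trigger-sharing loop pattern.
    """

    n_documents: int = 10
    sentences_per_document: int = 5
    event_frequencies: dict[str, float] = field(
        default_factory=lambda: dict(DEFAULT_EVENT_FREQUENCIES)
    )
    trigger_vocab: dict[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_TRIGGER_VOCAB)
    )
    protein_pool: tuple[str, ...] = DEFAULT_PROTEIN_POOL
    nesting_probability: float = 0.5
    merged_loop_probability: float = 0.15
    span_inconsistency_rate: float = 0.0
    #: regulation verbs that attach their subject as CAUSE; keeping the
    #: choice a deterministic function of the verb makes the corpus
    #: realisable by a model conditioning on lexical features
    causal_verbs: frozenset[str] = frozenset({"enhanced", "suppressed", "modulated"})
    seed: int = 0

    def __post_init__(self) -> None:
        for name in (
            "nesting_probability",
            "merged_loop_probability",
            "span_inconsistency_rate",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for etype, freq in self.event_frequencies.items():
            if freq > 0 and not self.trigger_vocab.get(etype):
                raise ValueError(f"no trigger vocabulary for active type {etype}")


# ---------------------------------------------------------------------------
# sentence assembly

class _SentenceBuilder:
    """Accumulates tokens, pre-merge dependencies, mentions and events."""

    def __init__(self) -> None:
        self.tokens: list[tuple[str, str, str]] = []  # surface, baseform, pos
        self.deps: list[tuple[int, int, str]] = []  # gov, dep, rel (0-based)
        self.proteins: list[tuple[int, int, str]] = []  # first_tok, last_tok, name
        # trigger token range (inclusive), type, args [(role, ref)]
        self.events: list[tuple[int, int, str, list[tuple[str, object]]]] = []

    def add(
        self,
        surface: str,
        base: str | None = None,
        pos: str = "NN",
        head: int | None = None,
        rel: str | None = None,
    ) -> int:
        idx = len(self.tokens)
        self.tokens.append((surface, base if base is not None else surface.lower(), pos))
        if head is not None and rel is not None:
            self.deps.append((head, idx, rel))
        return idx

    def add_protein(self, name: str) -> int:
        """Add a protein mention (possibly multi-word); returns its head token."""
        words = name.split(" ")
        first = len(self.tokens)
        for k, wsurf in enumerate(words):
            self.add(wsurf, wsurf.lower(), "NN")
            if k > 0:
                # internal noun-compound edge to the mention's last word
                self.deps.append((first + len(words) - 1, first + k - 1, "nn"))
        last = len(self.tokens) - 1
        self.proteins.append((first, last, name))
        return last

    def add_event(
        self,
        trig_first: int,
        trig_last: int,
        etype: str,
        args: list[tuple[str, object]],
    ) -> int:
        self.events.append((trig_first, trig_last, etype, args))
        return len(self.events) - 1


def _pick(rng: random.Random, seq: Sequence[str]) -> str:
    return seq[rng.randrange(len(seq))]


def _reg_vocab(cfg: GeneratorConfig, etype: str, multiword_ok: bool) -> list[str]:
    # 'overexpressed' is reserved for the merged-loop template
    return [w for w in cfg.trigger_vocab[etype] if w != "overexpressed"]


# template builders -----------------------------------------------------

def _t_plain_passive(b: _SentenceBuilder, rng: random.Random, cfg: GeneratorConfig, etype: str) -> None:
    # "<P> was expressed ."
    eds = [w for w in cfg.trigger_vocab[etype] if w.endswith("ed")]
    if not eds:
        _t_nominal_of(b, rng, cfg, etype)
        return
    trig = _pick(rng, eds)
    p = b.add_protein(_pick(rng, cfg.protein_pool))
    was = b.add("was", "be", "VBD")
    v = b.add(trig, trig[:-2], "VBN")
    b.deps.append((v, p, "nsubjpass"))
    b.deps.append((v, was, "auxpass"))
    b.add(".", ".", ".")
    pid = len(b.proteins) - 1
    b.add_event(v, v, etype, [(THEME, ("P", pid))])


def _t_nominal_of(b: _SentenceBuilder, rng: random.Random, cfg: GeneratorConfig, etype: str) -> None:
    # "<trigger> of <P> was observed ."
    trig = _pick(rng, [w for w in cfg.trigger_vocab[etype] if not w.endswith(("ed", "ds"))] or cfg.trigger_vocab[etype])
    t = b.add(trig, trig, "NN")
    of = b.add("of", "of", "IN", head=t, rel="prep")
    p = b.add_protein(_pick(rng, cfg.protein_pool))
    b.deps.append((of, p, "pobj"))
    was = b.add("was", "be", "VBD")
    obs = b.add("observed", "observe", "VBN")
    b.deps.append((obs, t, "nsubjpass"))
    b.deps.append((obs, was, "auxpass"))
    b.add(".", ".", ".")
    pid = len(b.proteins) - 1
    b.add_event(t, t, etype, [(THEME, ("P", pid))])


def _t_shared_trigger(b: _SentenceBuilder, rng: random.Random, cfg: GeneratorConfig, etype: str) -> None:
    # "mRNA expression of <P> was observed ." — 'expression' anchors both
    # Transcription and Gene Expression (multi-label node)
    m = b.add("mRNA", "mrna", "NN")
    t = b.add("expression", "expression", "NN")
    b.deps.append((t, m, "nn"))
    of = b.add("of", "of", "IN", head=t, rel="prep")
    p = b.add_protein(_pick(rng, cfg.protein_pool))
    b.deps.append((of, p, "pobj"))
    was = b.add("was", "be", "VBD")
    obs = b.add("observed", "observe", "VBN")
    b.deps.append((obs, t, "nsubjpass"))
    b.deps.append((obs, was, "auxpass"))
    b.add(".", ".", ".")
    pid = len(b.proteins) - 1
    b.add_event(t, t, TRANSCRIPTION, [(THEME, ("P", pid))])
    b.add_event(t, t, GENE_EXPRESSION, [(THEME, ("P", pid))])


def _t_binding(b: _SentenceBuilder, rng: random.Random, cfg: GeneratorConfig, etype: str) -> None:
    # "<P1> binds <P2> ."
    p1 = b.add_protein(_pick(rng, cfg.protein_pool))
    v = b.add("binds", "bind", "VBZ")
    p2 = b.add_protein(_pick(rng, cfg.protein_pool))
    b.deps.append((v, p1, "nsubj"))
    b.deps.append((v, p2, "dobj"))
    b.add(".", ".", ".")
    b.add_event(v, v, BINDING, [(THEME, ("P", 0)), (THEME, ("P", 1))])


def _t_reg_nested(b: _SentenceBuilder, rng: random.Random, cfg: GeneratorConfig, etype: str) -> None:
    # "<P1> <verb> the expression of <P2> ."
    verb = _pick(rng, [w for w in _reg_vocab(cfg, etype, False) if w.endswith("ed")])
    p1 = b.add_protein(_pick(rng, cfg.protein_pool))
    v = b.add(verb, verb[:-1] if verb.endswith("ed") else verb, "VBD")
    b.deps.append((v, p1, "nsubj"))
    the = b.add("the", "the", "DT")
    expr = b.add("expression", "expression", "NN")
    b.deps.append((expr, the, "det"))
    b.deps.append((v, expr, "dobj"))
    of = b.add("of", "of", "IN", head=expr, rel="prep")
    p2 = b.add_protein(_pick(rng, cfg.protein_pool))
    b.deps.append((of, p2, "pobj"))
    b.add(".", ".", ".")
    ge = b.add_event(expr, expr, GENE_EXPRESSION, [(THEME, ("P", 1))])
    args: list[tuple[str, object]] = [(THEME, ("E", ge))]
    if verb in cfg.causal_verbs:
        args.append((CAUSE, ("P", 0)))
    b.add_event(v, v, etype, args)


def _t_reg_multiword(b: _SentenceBuilder, rng: random.Random, cfg: GeneratorConfig, etype: str) -> None:
    # "<P1> showed <adj> levels of <P2> ." — multi-word trigger "<adj> levels"
    adj = _pick(rng, [w for w in _reg_vocab(cfg, etype, True) if w.endswith("d")])
    p1 = b.add_protein(_pick(rng, cfg.protein_pool))
    v = b.add("showed", "show", "VBD")
    b.deps.append((v, p1, "nsubj"))
    a = b.add(adj, adj[:-1] if adj.endswith("ed") else adj, "VBN")
    lv = b.add("levels", "level", "NNS")
    b.deps.append((lv, a, "amod"))
    b.deps.append((v, lv, "dobj"))
    of = b.add("of", "of", "IN", head=lv, rel="prep")
    p2 = b.add_protein(_pick(rng, cfg.protein_pool))
    b.deps.append((of, p2, "pobj"))
    b.add(".", ".", ".")
    b.add_event(a, lv, etype, [(THEME, ("P", 1))])


def _t_merged_loop(b: _SentenceBuilder, rng: random.Random, cfg: GeneratorConfig, etype: str) -> None:
    # "<P> was overexpressed ." — GE plus PR taking the GE as THEME,
    # sharing the trigger word (loop pattern)
    p = b.add_protein(_pick(rng, cfg.protein_pool))
    was = b.add("was", "be", "VBD")
    v = b.add("overexpressed", "overexpress", "VBN")
    b.deps.append((v, p, "nsubjpass"))
    b.deps.append((v, was, "auxpass"))
    b.add(".", ".", ".")
    ge = b.add_event(v, v, GENE_EXPRESSION, [(THEME, ("P", 0))])
    b.add_event(v, v, POSITIVE_REGULATION, [(THEME, ("E", ge))])


def _choose_template(
    rng: random.Random, cfg: GeneratorConfig, etype: str
) -> Callable[[_SentenceBuilder, random.Random, GeneratorConfig, str], None]:
    if etype == BINDING:
        return _t_binding
    if etype == TRANSCRIPTION:
        return _t_shared_trigger
    if etype in (PHOSPHORYLATION, LOCALIZATION, PROTEIN_CATABOLISM):
        return _t_nominal_of
    if etype == GENE_EXPRESSION:
        return _t_plain_passive
    # event-taking types
    if etype == POSITIVE_REGULATION and rng.random() < cfg.merged_loop_probability:
        return _t_merged_loop
    if rng.random() < cfg.nesting_probability:
        return _t_reg_nested
    return _t_reg_multiword


# ---------------------------------------------------------------------------
# document assembly

def _build_document(doc_id: str, builders: list[_SentenceBuilder]) -> Document:
    text_parts: list[str] = []
    tok_lines: list[str] = []
    dep_lines: list[str] = []
    a1_lines: list[str] = []
    a2_t_lines: list[str] = []
    a2_e_lines: list[str] = []
    offset = 0
    t_counter = 1
    trig_counter = 1000  # trigger T-ids start high to stay clear of a1 ids
    e_counter = 1

    for b in builders:
        starts: list[int] = []
        for surface, base, pos in b.tokens:
            starts.append(offset)
            text_parts.append(surface)
            tok_lines.append(f"{surface}\t{base}\t{pos}")
            offset += len(surface) + 1
        tok_lines.append("")
        for gov, dep, rel in sorted(b.deps):
            dep_lines.append(
                f"{rel}({b.tokens[gov][0]}-{gov + 1}, {b.tokens[dep][0]}-{dep + 1})"
            )
        dep_lines.append("")

        protein_ids: list[str] = []
        for first, last, name in b.proteins:
            start = starts[first]
            end = starts[last] + len(b.tokens[last][0])
            tid = f"T{t_counter}"
            t_counter += 1
            protein_ids.append(tid)
            a1_lines.append(f"{tid}\tProtein {start} {end}\t{name}")

        event_ids: list[str] = []
        trig_ids: dict[tuple[str, int, int], str] = {}
        for trig_first, trig_last, etype, _args in b.events:
            start = starts[trig_first]
            end = starts[trig_last] + len(b.tokens[trig_last][0])
            key = (etype, start, end)
            if key not in trig_ids:
                tid = f"T{trig_counter}"
                trig_counter += 1
                trig_ids[key] = tid
                trig_text = " ".join(
                    b.tokens[k][0] for k in range(trig_first, trig_last + 1)
                )
                a2_t_lines.append(f"{tid}\t{etype} {start} {end}\t{trig_text}")
            event_ids.append(f"E{e_counter}")
            e_counter += 1
        for ev_idx, (trig_first, trig_last, etype, args) in enumerate(b.events):
            start = starts[trig_first]
            end = starts[trig_last] + len(b.tokens[trig_last][0])
            parts = [f"{event_ids[ev_idx]}\t{etype}:{trig_ids[(etype, start, end)]}"]
            theme_n = 0
            for role, ref in args:
                kind, local = ref  # type: ignore[misc]
                target = protein_ids[local] if kind == "P" else event_ids[local]
                if role == THEME:
                    theme_n += 1
                    label = "Theme" if theme_n == 1 else f"Theme{theme_n}"
                else:
                    label = "Cause"
                parts.append(f"{label}:{target}")
            a2_e_lines.append(parts[0] + " " + " ".join(parts[1:]))

    txt = " ".join(text_parts)
    doc = read_standoff_document(
        doc_id,
        txt,
        "".join(l + "\n" for l in a1_lines),
        "".join(l + "\n" for l in a2_t_lines + a2_e_lines),
    )
    attach_sentences(doc, "\n".join(tok_lines) + "\n", "\n".join(dep_lines) + "\n")
    return doc


def generate_corpus(cfg: GeneratorConfig) -> list[Document]:
    """Generate a corpus of documents; identical config → identical corpus."""
    rng = random.Random(cfg.seed)
    types = sorted(cfg.event_frequencies)
    weights = [cfg.event_frequencies[t] for t in types]
    docs: list[Document] = []
    for d in range(cfg.n_documents):
        builders = []
        for _s in range(cfg.sentences_per_document):
            etype = rng.choices(types, weights=weights, k=1)[0]
            b = _SentenceBuilder()
            _choose_template(rng, cfg, etype)(b, rng, cfg, etype)
            builders.append(b)
        docs.append(_build_document(f"SYN{d:04d}", builders))
    if cfg.span_inconsistency_rate > 0:
        docs = inject_span_inconsistency(docs, cfg.span_inconsistency_rate, cfg.seed + 1)
    return docs


def eligible_for_span_flip(ev) -> bool:
    """Multi-word triggers annotated under the head-word convention."""
    return len(tokenize(ev.trigger_text)) >= 2


def inject_span_inconsistency(
    corpus: Sequence[Document], rate: float, seed: int = 0
) -> list[Document]:
    """Re-annotate a seeded random fraction of eligible triggers.

    Eligible triggers are multi-word spans; flipping replaces the span
    with its first (modifier) word, leaving the text unchanged — the
    modifier-word annotation convention.  Returns new documents.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError(f"rate must lie in [0, 1], got {rate}")
    rng = random.Random(seed)
    out: list[Document] = []
    for doc in corpus:
        new_events = {}
        for eid in sorted(doc.events):
            ev = doc.events[eid]
            if eligible_for_span_flip(ev) and rng.random() < rate:
                first, f_start, f_end = tokenize(ev.trigger_text, ev.trigger_start)[0]
                ev = replace(
                    ev, trigger_start=f_start, trigger_end=f_end, trigger_text=first
                )
            new_events[eid] = ev
        new_doc = Document(doc.id, doc.text, doc.sentences, dict(doc.proteins), new_events)
        out.append(new_doc)
    return out
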