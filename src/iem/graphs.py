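"""Conversion between event annotations and per-sentence labeled graphs.

Nodes are anchor words carrying sets of event-type labels (possibly
composite, e.g. the merged Gene Expression / Positive Regulation label);
edges are ordered token pairs labeled THEME or CAUSE (absence = negative).
Multi-word triggers are anchored at their syntactic head word; trigger-
sharing GE/PR loops become merged events; remaining loops are removed
and cyclic role-edge graphs are discarded.
"""

from __future__ import annotations

import itertools
import json
import logging
from dataclasses import dataclass, field
from typing import Callable, Iterable, Sequence

import networkx as nx

from .ontology import (
    BINDING,
    CAUSE,
    EVENT_TAKING_TYPES,
    GENE_EXPRESSION,
    MERGED_GE_PR,
    PLAIN_TYPES,
    POSITIVE_REGULATION,
    THEME,
    composite_components,
    is_composite,
)
from .standoff import DependencyGraph, Document, EventAnnotation, Sentence, Token

logger = logging.getLogger(__name__)


class _Discarded:
    """Sentinel for sentences whose role-edge graph is cyclic."""

    def __repr__(self) -> str:  # pragma: no cover
        return "DISCARDED"

    def __bool__(self) -> bool:
        return False


DISCARDED = _Discarded()

AnchorRule = Callable[[int, int, Sequence[Token], DependencyGraph], int]


@dataclass
class EventGraph:
    """Labeled graph over one sentence: the latent structure y.

    ``node_labels`` maps token index -> set of event-type labels;
    ``edge_labels`` maps ordered (source, target) -> role.  Each ordered
    pair carries at most one role.
    """

    sentence_index: int = 0
    node_labels: dict[int, frozenset[str]] = field(default_factory=dict)
    edge_labels: dict[tuple[int, int], str] = field(default_factory=dict)

    def anchors(self) -> set[int]:
        return {i for i, labels in self.node_labels.items() if labels}

    def anchors_of_type(self, event_type: str) -> set[int]:
        """Anchors labeled with *event_type*, counting composite components."""
        out = set()
        for i, labels in self.node_labels.items():
            for lab in labels:
                if event_type in composite_components(lab):
                    out.add(i)
        return out

    def out_edges(self, i: int) -> list[tuple[int, str]]:
        return sorted(
            (j, role) for (s, j), role in self.edge_labels.items() if s == i
        )

    def role_digraph(self) -> nx.DiGraph:
        g = nx.DiGraph()
        g.add_nodes_from(self.node_labels)
        g.add_edges_from((i, j) for (i, j) in self.edge_labels)
        return g

    def to_json(self) -> str:
        """One JSON line (debug dumps and E-step audit trails)."""
        return json.dumps(
            {
                "sentence": self.sentence_index,
                "nodes": {str(i): sorted(l) for i, l in sorted(self.node_labels.items())},
                "edges": {f"{i}->{j}": r for (i, j), r in sorted(self.edge_labels.items())},
            },
            sort_keys=True,
        )


def head_word(
    span_start: int,
    span_end: int,
    tokens: Sequence[Token],
    dg: DependencyGraph,
) -> int:
    """Head-Word rule: the in-span token whose governor lies outside the span.

    Ties (several governor-external or governor-less tokens) break to the
    rightmost.  A span covering no token is an error.
    """
    in_span = [
        t.index
        for t in tokens
        if t.char_start < span_end and t.char_end > span_start
    ]
    if not in_span:
        raise ValueError(f"span [{span_start},{span_end}) covers no token")
    if len(in_span) == 1:
        return in_span[0]
    span_set = set(in_span)
    heads = []
    for i in in_span:
        governors = [g for g, _rel in dg.governors_of(i)]
        if not governors or any(g not in span_set for g in governors):
            heads.append(i)
    return max(heads) if heads else max(in_span)


def _anchor_of_event(
    ev: EventAnnotation, sentence: Sentence, anchor_rule: AnchorRule
) -> int:
    return anchor_rule(ev.trigger_start, ev.trigger_end, sentence.tokens, sentence.deps)


def events_to_graph(
    doc: Document,
    sentence_index: int,
    anchor_rule: AnchorRule = head_word,
    use_merged: bool = True,
) -> EventGraph | _Discarded:
    """Convert a sentence's gold events into an :class:`EventGraph`.

    GE/PR trigger-sharing loops become single merged-label nodes when
    ``use_merged``; any remaining loop edges are removed; a cyclic
    role-edge graph yields :data:`DISCARDED`.  Events whose arguments
    resolve outside the sentence are skipped with a warning (the graph is
    strictly per-sentence).
    """
    sentence = doc.sentences[sentence_index]
    in_sentence = {
        eid: ev
        for eid, ev in doc.events.items()
        if doc.sentence_of_span(ev.trigger_start, ev.trigger_end) == sentence_index
    }

    anchors: dict[str, int] = {}
    for eid, ev in in_sentence.items():
        anchors[eid] = _anchor_of_event(ev, sentence, anchor_rule)

    node_labels: dict[int, set[str]] = {}
    edge_labels: dict[tuple[int, int], str] = {}
    for eid, ev in in_sentence.items():
        targets: list[tuple[str, int]] = []
        ok = True
        for role, target in ev.args:
            if target.startswith("T"):
                tok = doc.token_of_protein(sentence_index, target)
                if tok is None:
                    ok = False
                    break
                targets.append((role, tok))
            else:
                if target not in in_sentence:
                    ok = False
                    break
                targets.append((role, anchors[target]))
        if not ok:
            logger.warning(
                "%s: event %s has cross-sentence argument; skipped", doc.id, eid
            )
            continue
        i = anchors[eid]
        node_labels.setdefault(i, set()).add(ev.event_type)
        for role, j in targets:
            prev = edge_labels.get((i, j))
            if prev is None or (prev == CAUSE and role == THEME):
                edge_labels[(i, j)] = role  # at most one role; THEME wins conflicts

    # merged GE/PR loops
    if use_merged:
        for i, labels in list(node_labels.items()):
            if (
                GENE_EXPRESSION in labels
                and POSITIVE_REGULATION in labels
                and edge_labels.get((i, i)) == THEME
            ):
                labels.discard(GENE_EXPRESSION)
                labels.discard(POSITIVE_REGULATION)
                labels.add(MERGED_GE_PR)
                del edge_labels[(i, i)]

    # remove remaining loops
    for (i, j) in [k for k in edge_labels if k[0] == k[1]]:
        del edge_labels[(i, j)]

    g = EventGraph(
        sentence_index,
        {i: frozenset(l) for i, l in node_labels.items() if l},
        edge_labels,
    )
    if not nx.is_directed_acyclic_graph(g.role_digraph()):
        return DISCARDED
    return g


def _protein_tokens(sentence: Sentence) -> dict[int, str]:
    return {t.index: t.protein_id for t in sentence.tokens if t.protein_id}


def graph_to_events(
    g: EventGraph, sentence: Sentence, id_prefix: str = "E"
) -> list[EventAnnotation]:
    """Derive event annotations from a labeled graph.

    Nodes are processed in topological order of the role-edge graph
    (children first).  Plain protein-taking types emit one event per
    protein THEME edge; Binding emits a single event carrying all its
    protein THEME edges; event-taking types emit the cross-product of
    THEME options (protein targets plus every event anchored at event
    THEME targets) with CAUSE options (targets plus "absent").  Merged
    labels expand into a GE event plus a PR event taking it as THEME;
    CAUSE edges of the merged node attach to the PR component.

    Output triggers are the anchor word's span (span recovery is a
    non-goal).  A labeled node with no THEME edge violates the graph
    contract.
    """
    proteins = _protein_tokens(sentence)
    digraph = g.role_digraph()
    order = [n for n in nx.topological_sort(digraph)]
    order.reverse()  # children before parents

    events_at: dict[int, list[EventAnnotation]] = {i: [] for i in g.node_labels}
    out: list[EventAnnotation] = []
    counter = itertools.count(1)

    def emit(i: int, etype: str, args: list[tuple[str, str]]) -> EventAnnotation:
        tok = sentence.tokens[i]
        ev = EventAnnotation(
            f"{id_prefix}{next(counter)}",
            etype,
            tok.char_start,
            tok.char_end,
            tok.surface,
            tuple(args),
        )
        out.append(ev)
        events_at[i].append(ev)
        return ev

    for i in order:
        labels = g.node_labels.get(i)
        if not labels:
            continue
        edges = g.out_edges(i)
        if not any(role == THEME for _j, role in edges):
            raise ValueError(f"labeled node {i} has no THEME edge")
        theme_prot = [j for j, r in edges if r == THEME and j in proteins]
        theme_evt_nodes = [j for j, r in edges if r == THEME and j not in proteins]
        cause_prot = [j for j, r in edges if r == CAUSE and j in proteins]
        cause_evt_nodes = [j for j, r in edges if r == CAUSE and j not in proteins]

        for label in sorted(labels):
            if label == MERGED_GE_PR:
                for j in theme_prot:
                    ge = emit(i, GENE_EXPRESSION, [(THEME, proteins[j])])
                    cause_args: list[list[tuple[str, str]]] = [[]]
                    options: list[tuple[str, str]] = [
                        (CAUSE, proteins[j2]) for j2 in cause_prot
                    ] + [
                        (CAUSE, ev.id)
                        for j2 in cause_evt_nodes
                        for ev in events_at.get(j2, [])
                    ]
                    if options:
                        cause_args = [[opt] for opt in options]
                    for ca in cause_args:
                        emit(i, POSITIVE_REGULATION, [(THEME, ge.id)] + ca)
                continue
            if is_composite(label):
                # open composite label without a defined expansion: expand
                # component-wise as independent labels
                for comp in composite_components(label):
                    _emit_simple(
                        comp, i, emit, proteins, events_at,
                        theme_prot, theme_evt_nodes, cause_prot, cause_evt_nodes,
                    )
                continue
            _emit_simple(
                label, i, emit, proteins, events_at,
                theme_prot, theme_evt_nodes, cause_prot, cause_evt_nodes,
            )
    return out


def _emit_simple(
    label: str,
    i: int,
    emit,
    proteins: dict[int, str],
    events_at: dict[int, list[EventAnnotation]],
    theme_prot: list[int],
    theme_evt_nodes: list[int],
    cause_prot: list[int],
    cause_evt_nodes: list[int],
) -> None:
    if label in PLAIN_TYPES:
        for j in theme_prot:
            emit(i, label, [(THEME, proteins[j])])
    elif label == BINDING:
        if theme_prot:
            emit(i, label, [(THEME, proteins[j]) for j in theme_prot])
    elif label in EVENT_TAKING_TYPES:
        theme_options: list[str] = [proteins[j] for j in theme_prot] + [
            ev.id for j in theme_evt_nodes for ev in events_at.get(j, [])
        ]
        # CAUSE edges, when present, are read as binding every emitted
        # event (an absent-CAUSE variant would break round-trip identity)
        cause_options: list[str | None] = [proteins[j] for j in cause_prot] + [
            ev.id for j in cause_evt_nodes for ev in events_at.get(j, [])
        ] or [None]
        for th in theme_options:
            for ca in cause_options:
                args = [(THEME, th)]
                if ca is not None:
                    args.append((CAUSE, ca))
                emit(i, label, args)
    else:
        raise ValueError(f"unknown event type label {label!r}")


def canonicalize_corpus(
    corpus: Iterable[Document],
    anchor_rule: AnchorRule = head_word,
) -> list[Document]:
    """Replace gold events by their graph round-trip (anchor-word triggers).

    Decoded predictions carry single-token trigger spans, so exact
    matching against raw multi-word gold spans is structurally
    impossible; canonicalised documents provide the comparable gold.
    """
    out = []
    for doc in corpus:
        evs = []
        for sent in doc.sentences:
            g = events_to_graph(doc, sent.index, anchor_rule, use_merged=True)
            if g is DISCARDED:
                continue
            evs.extend(graph_to_events(g, sent, id_prefix=f"G{sent.index}_"))
        out.append(
            Document(doc.id, doc.text, doc.sentences, dict(doc.proteins),
                     {ev.id: ev for ev in evs})
        )
    return out


def reconstruct_annotations(
    corpus: Iterable[Document],
    use_merged: bool = True,
    anchor_rule: AnchorRule = head_word,
) -> dict[str, list[EventAnnotation]]:
    """Round-trip gold annotations through the graph representation.

    Returns reconstructed events per document id; DISCARDED sentences
    contribute no events.  Events that cannot be encoded in graphs do not
    survive reconstruction.
    """
    out: dict[str, list[EventAnnotation]] = {}
    for doc in corpus:
        evs: list[EventAnnotation] = []
        for sent in doc.sentences:
            g = events_to_graph(doc, sent.index, anchor_rule, use_merged)
            if g is DISCARDED:
                continue
            evs.extend(graph_to_events(g, sent, id_prefix=f"R{sent.index}_"))
        out[doc.id] = evs
    return out
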