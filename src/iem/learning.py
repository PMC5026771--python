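"""Training: cost-sensitive Passive-Aggressive baseline and informed EM.

The baseline takes repeated passes over the corpus; on each mistaken
sentence it applies a Passive-Aggressive update — the minimal-norm weight
change making the gold assignment outscore the prediction by at least the
cost of the mistake, where false negatives cost ``fn_cost_ratio`` (3.8)
times false positives.  After each pass the running average of all
interim weight vectors is stored (averaging reduces over-fitting).

The informed EM algorithm maintains an *adjusted* copy of the gold
graphs.  After ``init_rounds`` supervised rounds it alternates an E step
— replace a sentence's adjusted graph with the model's prediction when
the prediction differs and passes all active constraints (basic,
confidence, optional non-overlapping, distance) — with an M step, a PA
pass over the adjusted corpus in which sentences whose graphs were ever
updated incur ``updated_cost_multiplier`` (10x) the usual cost.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .features import CandidateMask, FeatureVector, candidate_mask, edge_feature_vector, node_feature_vector, token_distance
from .graphs import DISCARDED, EventGraph, events_to_graph, graph_to_events, head_word
from .lexicon import LexiconPair
from .ontology import composite_components
from .scoring import (
    Assignment,
    NEGATIVE,
    WeightVectors,
    decode,
    sparse_dot,
)
from .standoff import Document, EventAnnotation, Sentence

_EPS = 1e-8


@dataclass
class TrainingConfig:
    """Hyper-parameters of both learning algorithms.

    ``fn_cost_ratio`` penalises false-negative triggers and edges 3.8
    times more heavily than false positives; ``alpha`` is the confidence
    constraint constant (minimum relative score improvement an E-step
    update must show); ``beta`` the distance constraint constant in word
    tokens; ``updated_cost_multiplier`` the extra weight (10x) given to
    mistakes on sentences whose adjusted graphs were updated.
    """

    passes: int = 20
    fn_cost_ratio: float = 3.8
    init_rounds: int = 5
    updated_cost_multiplier: float = 10.0
    alpha: float = 0.3
    beta: float = 2.0
    use_noc: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.passes < self.init_rounds:
            raise ValueError("passes must be >= init_rounds")
        if self.alpha < 0 or self.beta < 0:
            raise ValueError("alpha and beta must be non-negative")


# ---------------------------------------------------------------------------
# prepared sentences

@dataclass
class PreparedSentence:
    """A sentence with its mask, feature cache and gold structures."""

    doc_id: str
    sentence: Sentence
    mask: CandidateMask
    node_phis: dict[int, FeatureVector]
    edge_phis: dict[tuple[int, int], FeatureVector]
    gold_graph: EventGraph
    gold_assignment: Assignment
    gold_events: list[EventAnnotation]


def graph_to_assignment(g: EventGraph, mask: CandidateMask) -> Assignment:
    """Project an event graph onto a candidate mask as an assignment.

    Gold labels outside the mask cannot be represented and are dropped
    (the lexicon filter's coverage penalty).
    """
    a = Assignment.all_negative(mask)
    for (i, e) in a.node_labels:
        if e in g.node_labels.get(i, ()):
            a.node_labels[(i, e)] = True
    for (i, j) in a.edge_labels:
        role = g.edge_labels.get((i, j))
        if role is not None:
            a.edge_labels[(i, j)] = role
    return a


def assignment_to_graph(a: Assignment, sentence_index: int = 0) -> EventGraph:
    nodes = {}
    for (i, _e), pos in a.node_labels.items():
        if pos:
            nodes[i] = a.positive_types(i)
    return EventGraph(sentence_index, nodes, dict(a.role_edges()))


def prepare_corpus(
    corpus: Iterable[Document], lex: LexiconPair
) -> list[PreparedSentence]:
    """Feature-extract and gold-convert every usable sentence.

    Sentences whose gold graphs are DISCARDED (cyclic) are skipped.
    """
    prepared: list[PreparedSentence] = []
    for doc in corpus:
        for sent in doc.sentences:
            g = events_to_graph(doc, sent.index, head_word, use_merged=True)
            if g is DISCARDED:
                continue
            mask = candidate_mask(sent, lex)
            node_phis = {i: node_feature_vector(i, sent, lex) for i in mask.node_candidates}
            edge_phis = {
                (i, j): edge_feature_vector(i, j, sent, lex)
                for (i, j) in mask.edge_candidates
            }
            gold_events = [
                ev
                for ev in doc.events.values()
                if doc.sentence_of_span(ev.trigger_start, ev.trigger_end) == sent.index
            ]
            prepared.append(
                PreparedSentence(
                    doc.id,
                    sent,
                    mask,
                    node_phis,
                    edge_phis,
                    g,
                    graph_to_assignment(g, mask),
                    gold_events,
                )
            )
    return prepared


# ---------------------------------------------------------------------------
# PA machinery

def assignment_cost(gold: Assignment, pred: Assignment, fn_ratio: float) -> float:
    """Cost of predicting *pred* against *gold* on a shared mask.

    False positives cost 1, false negatives ``fn_ratio``; a role-label
    substitution (THEME vs CAUSE) counts as one of each.
    """
    if set(gold.node_labels) != set(pred.node_labels) or set(gold.edge_labels) != set(
        pred.edge_labels
    ):
        raise ValueError("assignments defined on different masks")
    fp = fn = 0
    for key, g_pos in gold.node_labels.items():
        p_pos = pred.node_labels[key]
        if p_pos and not g_pos:
            fp += 1
        elif g_pos and not p_pos:
            fn += 1
    for key, g_lab in gold.edge_labels.items():
        p_lab = pred.edge_labels[key]
        if g_lab == p_lab:
            continue
        if g_lab == NEGATIVE:
            fp += 1
        elif p_lab == NEGATIVE:
            fn += 1
        else:
            fp += 1
            fn += 1
    return fp + fn_ratio * fn


def raw_score(
    a: Assignment,
    w: WeightVectors,
    node_phis: Mapping[int, FeatureVector],
    edge_phis: Mapping[tuple[int, int], FeatureVector],
) -> float:
    """Assignment score without the validity gate (sum of all terms)."""
    total = 0.0
    for (i, e), pos in a.node_labels.items():
        s = sparse_dot(w.node_weights.get(e, {}), node_phis[i])
        total += s if pos else -s
    for (i, j), lab in a.edge_labels.items():
        total += sparse_dot(w.edge_weights.get(lab, {}), edge_phis[(i, j)])
    return total


def _delta_features(
    gold: Assignment,
    pred: Assignment,
    node_phis: Mapping[int, FeatureVector],
    edge_phis: Mapping[tuple[int, int], FeatureVector],
) -> WeightVectors:
    """Ψ(gold) − Ψ(pred): the joint feature-map difference."""
    delta = WeightVectors()
    for (i, e), g_pos in gold.node_labels.items():
        p_pos = pred.node_labels[(i, e)]
        if g_pos == p_pos:
            continue
        coeff = 2.0 if g_pos else -2.0
        vec = delta.node_vec(e)
        for k, v in node_phis[i].items():
            vec[k] = vec.get(k, 0.0) + coeff * v
    for (i, j), g_lab in gold.edge_labels.items():
        p_lab = pred.edge_labels[(i, j)]
        if g_lab == p_lab:
            continue
        phi = edge_phis[(i, j)]
        vec = delta.edge_vec(g_lab)
        for k, v in phi.items():
            vec[k] = vec.get(k, 0.0) + v
        vec = delta.edge_vec(p_lab)
        for k, v in phi.items():
            vec[k] = vec.get(k, 0.0) - v
    return delta


def pa_tau(
    w: WeightVectors,
    gold: Assignment,
    pred: Assignment,
    cost: float,
    node_phis: Mapping[int, FeatureVector],
    edge_phis: Mapping[tuple[int, int], FeatureVector],
) -> tuple[float, WeightVectors]:
    """Closed-form PA step size and update direction Δ."""
    delta = _delta_features(gold, pred, node_phis, edge_phis)
    nsq = delta.norm_sq()
    if nsq == 0.0:
        return 0.0, delta
    loss = (
        raw_score(pred, w, node_phis, edge_phis)
        - raw_score(gold, w, node_phis, edge_phis)
        + cost
    )
    return max(0.0, loss) / nsq, delta


def pa_update(
    w: WeightVectors,
    gold: Assignment,
    pred: Assignment,
    cost: float,
    node_phis: Mapping[int, FeatureVector],
    edge_phis: Mapping[tuple[int, int], FeatureVector],
) -> WeightVectors:
    """Functional PA update: returns ``w + τΔ`` (``w`` unchanged).

    After the update the gold assignment outscores the prediction by at
    least ``cost`` under the pre-update feature maps.
    """
    tau, delta = pa_tau(w, gold, pred, cost, node_phis, edge_phis)
    out = w.copy()
    if tau > 0.0:
        out.add_scaled(delta, tau)
    return out


# ---------------------------------------------------------------------------
# posterior constraints (E-step gates)

def canonical_structure(
    g: EventGraph | Assignment, sentence: Sentence, no_events: bool = False
) -> tuple[frozenset[str], frozenset[tuple[str, str, str]]]:
    """Typed event structure of a graph: (event types, argument triples).

    Argument triples are (parent event type, role, child kind) where the
    child kind is the protein mention id for protein arguments and the
    child's event type for event arguments.  Triggers are ignored.
    """
    if isinstance(g, Assignment):
        if g.no_events or no_events:
            return frozenset(), frozenset()
        g = assignment_to_graph(g, sentence.index)
    elif no_events:
        return frozenset(), frozenset()
    events = graph_to_events(g, sentence)
    by_id = {ev.id: ev for ev in events}
    types = frozenset(ev.event_type for ev in events)
    triples = set()
    for ev in events:
        for role, target in ev.args:
            child = by_id[target].event_type if target in by_id else target
            triples.add((ev.event_type, role, child))
    return types, frozenset(triples)


def basic_constraint(
    candidate: EventGraph | Assignment,
    gold: EventGraph,
    sentence: Sentence,
) -> bool:
    """Same event types and typed argument triples as the gold graph."""
    return canonical_structure(candidate, sentence) == canonical_structure(
        gold, sentence
    )


def confidence_constraint(
    candidate_score: float, current_score: float, alpha: float
) -> bool:
    """Relative score improvement of the candidate is at least *alpha*."""
    return (candidate_score - current_score) / max(abs(current_score), _EPS) >= alpha


def non_overlapping_constraint(
    candidate: EventGraph, gold_events: Sequence[EventAnnotation]
) -> bool:
    """Distinct same-type gold triggers need distinct candidate anchors.

    For each event type, the number of distinct candidate anchor words
    carrying it must reach the number of distinct gold trigger spans of
    that type.
    """
    spans_by_type: dict[str, set[tuple[int, int]]] = {}
    for ev in gold_events:
        spans_by_type.setdefault(ev.event_type, set()).add(
            (ev.trigger_start, ev.trigger_end)
        )
    for etype, spans in spans_by_type.items():
        if len(candidate.anchors_of_type(etype)) < len(spans):
            return False
    return True


def distance_constraint(
    candidate: EventGraph,
    current: EventGraph,
    beta: float,
    sentence: Sentence,
) -> bool:
    """Every current anchor has a same-type candidate anchor within *beta*.

    Distances are in word tokens (punctuation skipped).
    """
    current_types = set()
    for labels in current.node_labels.values():
        for lab in labels:
            current_types.update(composite_components(lab))
    for etype in current_types:
        cand_anchors = candidate.anchors_of_type(etype)
        for i in current.anchors_of_type(etype):
            if not cand_anchors:
                return False
            if min(token_distance(i, j, sentence) for j in cand_anchors) > beta:
                return False
    return True


# ---------------------------------------------------------------------------
# trainers

@dataclass
class UpdateRecord:
    """Audit-trail entry for one accepted E-step update."""

    round_no: int
    old_graph: EventGraph
    new_graph: EventGraph
    candidate_score: float
    current_score: float


@dataclass
class SentenceState:
    """Adjusted-annotation state of one sentence during informed EM."""

    adjusted: Assignment
    adjusted_graph: EventGraph
    updated: bool = False
    history: list[UpdateRecord] = field(default_factory=list)


@dataclass
class AdjustedCorpus:
    """The adjusted annotation set D' with its full update history."""

    states: list[SentenceState]
    prepared: list[PreparedSentence]
    updates_per_round: dict[int, int] = field(default_factory=dict)

    @property
    def total_updates(self) -> int:
        return sum(self.updates_per_round.values())


class _Averager:
    """Running average of interim weight vectors via the lazy sum trick.

    With sparse updates δ_n at step n, Σ_{k≤N} w_k = (N+1)·w_N − Σ n·δ_n.
    """

    def __init__(self) -> None:
        self.n = 0
        self.u = WeightVectors()

    def step(self) -> None:
        self.n += 1

    def record_update(self, delta: WeightVectors, tau: float) -> None:
        self.u.add_scaled(delta, self.n * tau)

    def average(self, w: WeightVectors) -> WeightVectors:
        if self.n == 0:
            return w.copy()
        avg = w.scaled((self.n + 1) / self.n)
        avg.add_scaled(self.u, -1.0 / self.n)
        return avg


def _train(
    prepared: list[PreparedSentence],
    config: TrainingConfig,
    e_step: bool,
) -> tuple[list[WeightVectors], AdjustedCorpus]:
    states = [
        SentenceState(ps.gold_assignment, ps.gold_graph) for ps in prepared
    ]
    corpus_state = AdjustedCorpus(states, prepared)
    w = WeightVectors()
    averager = _Averager()
    models: list[WeightVectors] = []

    for round_no in range(1, config.passes + 1):
        if e_step and round_no > config.init_rounds and models:
            model = models[-1]
            n_updates = 0
            for ps, st in zip(prepared, states):
                pred = decode(ps.sentence, model, ps.mask, ps.node_phis, ps.edge_phis)
                if pred.labels_equal(st.adjusted):
                    continue
                cand_graph = assignment_to_graph(pred, ps.sentence.index)
                if pred.no_events:
                    cand_graph = EventGraph(ps.sentence.index)
                if not basic_constraint(cand_graph, ps.gold_graph, ps.sentence):
                    continue
                cand_score = raw_score(pred, model, ps.node_phis, ps.edge_phis)
                cur_score = raw_score(st.adjusted, model, ps.node_phis, ps.edge_phis)
                if not confidence_constraint(cand_score, cur_score, config.alpha):
                    continue
                if config.use_noc and not non_overlapping_constraint(
                    cand_graph, ps.gold_events
                ):
                    continue
                if not distance_constraint(
                    cand_graph, st.adjusted_graph, config.beta, ps.sentence
                ):
                    continue
                st.history.append(
                    UpdateRecord(
                        round_no, st.adjusted_graph, cand_graph, cand_score, cur_score
                    )
                )
                st.adjusted = pred
                st.adjusted_graph = cand_graph
                st.updated = True
                n_updates += 1
            if n_updates:
                corpus_state.updates_per_round[round_no] = n_updates

        # M step: one PA pass over the (adjusted) corpus
        for ps, st in zip(prepared, states):
            averager.step()
            pred = decode(ps.sentence, w, ps.mask, ps.node_phis, ps.edge_phis)
            gold = st.adjusted
            if pred.labels_equal(gold):
                continue
            cost = assignment_cost(gold, pred, config.fn_cost_ratio)
            if st.updated:
                cost *= config.updated_cost_multiplier
            tau, delta = pa_tau(w, gold, pred, cost, ps.node_phis, ps.edge_phis)
            if tau > 0.0:
                w.add_scaled(delta, tau)
                averager.record_update(delta, tau)
        models.append(averager.average(w))

    return models, corpus_state


def train_baseline(
    prepared: list[PreparedSentence], config: TrainingConfig
) -> list[WeightVectors]:
    """Cost-sensitive PA baseline: one averaged model per pass."""
    models, _ = _train(prepared, config, e_step=False)
    return models


def informed_em(
    prepared: list[PreparedSentence], config: TrainingConfig
) -> tuple[list[WeightVectors], AdjustedCorpus]:
    """Informed EM: averaged models per round plus the adjusted corpus."""
    return _train(prepared, config, e_step=True)
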