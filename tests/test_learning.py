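"""Learning: costs, PA updates, baseline training, EM constraints."""

from __future__ import annotations

import random

import pytest

from iem.features import CandidateMask
from iem.graphs import EventGraph, events_to_graph
from iem.learning import (
    TrainingConfig,
    assignment_cost,
    basic_constraint,
    confidence_constraint,
    distance_constraint,
    informed_em,
    non_overlapping_constraint,
    pa_update,
    prepare_corpus,
    raw_score,
    train_baseline,
)
from iem.lexicon import LexiconPair
from iem.ontology import CAUSE, THEME
from iem.scoring import Assignment, NEGATIVE, WeightVectors, decode
from iem.standoff import EventAnnotation
from iem.synthetic import GeneratorConfig, generate_corpus
from conftest import make_sentence


def _mask():
    return CandidateMask(
        {0: frozenset({"Ty0"}), 1: frozenset({"Ty0"})},
        frozenset({(0, 2), (1, 2)}),
    )


class TestAssignmentCost:
    def test_identical_zero(self):
        a = Assignment.all_negative(_mask())
        assert assignment_cost(a, a, 3.8) == 0.0

    def test_missed_trigger_costs_ratio(self):
        gold = Assignment.all_negative(_mask())
        gold.node_labels[(0, "Ty0")] = True
        pred = Assignment.all_negative(_mask())
        assert assignment_cost(gold, pred, 3.8) == pytest.approx(3.8)

    def test_spurious_plus_missed_edge(self):
        gold = Assignment.all_negative(_mask())
        gold.edge_labels[(0, 2)] = THEME
        pred = Assignment.all_negative(_mask())
        pred.edge_labels[(1, 2)] = THEME
        assert assignment_cost(gold, pred, 3.8) == pytest.approx(1 + 3.8)

    def test_role_substitution_is_fp_plus_fn(self):
        gold = Assignment.all_negative(_mask())
        gold.edge_labels[(0, 2)] = THEME
        pred = Assignment.all_negative(_mask())
        pred.edge_labels[(0, 2)] = CAUSE
        assert assignment_cost(gold, pred, 3.8) == pytest.approx(1 + 3.8)

    def test_mask_mismatch_rejected(self):
        gold = Assignment.all_negative(_mask())
        with pytest.raises(ValueError, match="different masks"):
            assignment_cost(gold, Assignment({}, {}), 3.8)


class TestPAUpdate:
    def _phis(self):
        node_phis = {0: {"a": 1.0}, 1: {"b": 1.0}}
        edge_phis = {(0, 2): {"c": 1.0}, (1, 2): {"d": 1.0}}
        return node_phis, edge_phis

    def test_identical_assignments_no_change(self):
        a = Assignment.all_negative(_mask())
        node_phis, edge_phis = self._phis()
        w = WeightVectors()
        w.node_weights["Ty0"] = {"a": 1.0}
        out = pa_update(w, a, a, 0.0, node_phis, edge_phis)
        assert out.node_weights == w.node_weights

    def test_margin_met_under_old_feature_maps(self):
        rng = random.Random(0)
        node_phis, edge_phis = self._phis()
        for _ in range(50):
            gold = Assignment.all_negative(_mask())
            pred = Assignment.all_negative(_mask())
            gold.node_labels[(0, "Ty0")] = rng.random() < 0.5
            pred.node_labels[(0, "Ty0")] = rng.random() < 0.5
            gold.edge_labels[(0, 2)] = rng.choice([THEME, CAUSE, NEGATIVE])
            pred.edge_labels[(0, 2)] = rng.choice([THEME, CAUSE, NEGATIVE])
            if gold.labels_equal(pred):
                continue
            w = WeightVectors()
            w.node_weights["Ty0"] = {"a": rng.uniform(-2, 2)}
            w.edge_weights[THEME] = {"c": rng.uniform(-2, 2)}
            cost = assignment_cost(gold, pred, 3.8)
            new_w = pa_update(w, gold, pred, cost, node_phis, edge_phis)
            margin = raw_score(gold, new_w, node_phis, edge_phis) - raw_score(
                pred, new_w, node_phis, edge_phis
            )
            assert margin >= cost - 1e-9

    def test_tau_matches_hand_computed_closed_form(self):
        # single node feature differing: delta = +-2*phi, |delta|^2 = 4
        node_phis = {0: {"a": 1.0}}
        edge_phis = {(0, 1): {"c": 1.0}}
        mask = CandidateMask({0: frozenset({"Ty0"})}, frozenset({(0, 1)}))
        gold = Assignment.all_negative(mask)
        gold.node_labels[(0, "Ty0")] = True
        gold.edge_labels[(0, 1)] = THEME
        pred = Assignment.all_negative(mask)
        w = WeightVectors()  # zero: loss = 0 - 0 + cost
        cost = 2 * 3.8
        new_w = pa_update(w, gold, pred, cost, node_phis, edge_phis)
        # delta: node +2a, edge +c into THEME, -c into negative -> |d|^2 = 6
        tau = cost / 6.0
        assert new_w.node_weights["Ty0"]["a"] == pytest.approx(2 * tau)
        assert new_w.edge_weights[THEME]["c"] == pytest.approx(tau)
        assert new_w.edge_weights[NEGATIVE]["c"] == pytest.approx(-tau)


def _prepared(seed=0, n_docs=6, **kw):
    corpus = generate_corpus(
        GeneratorConfig(n_documents=n_docs, sentences_per_document=4, seed=seed, **kw)
    )
    lex = LexiconPair.build(corpus)
    return prepare_corpus(corpus, lex)


class TestTrainBaseline:
    def test_all_negative_gold_keeps_zero_model(self):
        # corpus without events: gold graphs are empty, model never updates
        corpus = generate_corpus(GeneratorConfig(n_documents=2, sentences_per_document=2, seed=1))
        for doc in corpus:
            doc.events = {}
        lex_src = generate_corpus(GeneratorConfig(n_documents=2, sentences_per_document=2, seed=1))
        lex = LexiconPair.build(lex_src)
        prepared = prepare_corpus(corpus, lex)
        models = train_baseline(prepared, TrainingConfig(passes=3, init_rounds=1))
        assert all(not m.norm_sq() for m in models)

    def test_separable_fixture_learned_by_second_pass(self):
        prepared = _prepared(seed=2, n_docs=2)
        cfg = TrainingConfig(passes=4, init_rounds=1)
        train_baseline(prepared, cfg)
        # run a fresh non-averaged training loop to convergence as oracle
        w = WeightVectors()
        from iem.learning import pa_tau

        for _ in range(8):
            mistakes = 0
            for ps in prepared:
                pred = decode(ps.sentence, w, ps.mask, ps.node_phis, ps.edge_phis)
                if pred.labels_equal(ps.gold_assignment):
                    continue
                mistakes += 1
                cost = assignment_cost(ps.gold_assignment, pred, 3.8)
                tau, delta = pa_tau(w, ps.gold_assignment, pred, cost, ps.node_phis, ps.edge_phis)
                w.add_scaled(delta, tau)
            if mistakes == 0:
                break
        assert mistakes == 0  # the fixture is separable

    def test_averaged_model_equals_explicit_accumulation(self):
        prepared = _prepared(seed=3, n_docs=2)
        cfg = TrainingConfig(passes=2, init_rounds=1)
        models = train_baseline(prepared, cfg)

        # explicit accumulator oracle
        from iem.learning import pa_tau

        w = WeightVectors()
        acc = WeightVectors()
        n = 0
        expected = []
        for _pass in range(cfg.passes):
            for ps in prepared:
                pred = decode(ps.sentence, w, ps.mask, ps.node_phis, ps.edge_phis)
                if not pred.labels_equal(ps.gold_assignment):
                    cost = assignment_cost(ps.gold_assignment, pred, cfg.fn_cost_ratio)
                    tau, delta = pa_tau(
                        w, ps.gold_assignment, pred, cost, ps.node_phis, ps.edge_phis
                    )
                    if tau > 0:
                        w.add_scaled(delta, tau)
                acc.add_scaled(w, 1.0)
                n += 1
            expected.append(acc.scaled(1.0 / n))
        for m, e in zip(models, expected):
            for etype in set(m.node_weights) | set(e.node_weights):
                for k in set(m.node_weights.get(etype, {})) | set(e.node_weights.get(etype, {})):
                    assert m.node_weights.get(etype, {}).get(k, 0.0) == pytest.approx(
                        e.node_weights.get(etype, {}).get(k, 0.0), abs=1e-9
                    )


class TestConstraints:
    def test_basic_identical_graphs(self, nested_doc):
        g = events_to_graph(nested_doc, 0)
        assert basic_constraint(g, g, nested_doc.sentences[0])

    def test_basic_allows_moved_trigger(self, nested_doc):
        sent = nested_doc.sentences[0]
        g = events_to_graph(nested_doc, 0)
        # move the PR anchor from 'enhanced' (1) to 'the' (2): same types,
        # same typed argument triples
        moved = EventGraph(
            0,
            {2: g.node_labels[1], 3: g.node_labels[3]},
            {(2, 3): THEME, (2, 0): CAUSE, (3, 5): THEME},
        )
        assert basic_constraint(moved, g, sent)

    def test_basic_rejects_dropped_event(self, nested_doc):
        sent = nested_doc.sentences[0]
        g = events_to_graph(nested_doc, 0)
        only_ge = EventGraph(0, {3: frozenset({"Gene_expression"})}, {(3, 5): THEME})
        assert not basic_constraint(only_ge, g, sent)

    def test_confidence_boundary(self):
        assert confidence_constraint(10.0, 10.0, 0.0)
        assert confidence_constraint(13.0, 10.0, 0.3)
        assert not confidence_constraint(12.9, 10.0, 0.3)

    def _sentence5_graphs(self):
        # "levels" (3) and "augmented" (8) anchor two PR events
        sent_words = [
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
        sent = make_sentence(sent_words, set(), proteins={0: "T1"})
        both = EventGraph(
            0,
            {3: frozenset({"Positive_regulation"}), 8: frozenset({"Positive_regulation"})},
            {(3, 0): THEME, (8, 0): THEME},
        )
        one = EventGraph(0, {8: frozenset({"Positive_regulation"})}, {(8, 0): THEME})
        gold_events = [
            EventAnnotation("E1", "Positive_regulation", 9, 20, "high levels", ((THEME, "T1"),)),
            EventAnnotation("E2", "Positive_regulation", 40, 49, "augmented", ((THEME, "T1"),)),
        ]
        return sent, both, one, gold_events

    def test_noc_rejects_collapsed_anchors(self):
        _sent, _both, one, gold_events = self._sentence5_graphs()
        assert not non_overlapping_constraint(one, gold_events)

    def test_noc_accepts_preserved_anchors(self):
        _sent, both, _one, gold_events = self._sentence5_graphs()
        assert non_overlapping_constraint(both, gold_events)

    def test_noc_vacuous_for_absent_type(self):
        _sent, both, _one, _ = self._sentence5_graphs()
        assert non_overlapping_constraint(both, [])

    def test_distance_identity_always_holds(self):
        sent, both, _one, _ = self._sentence5_graphs()
        assert distance_constraint(both, both, 0.0, sent)

    def test_distance_four_blocks_beta_three(self):
        sent, both, one, _ = self._sentence5_graphs()
        # dropping the 'levels' anchor leaves 'augmented' four away
        assert not distance_constraint(one, both, 3.0, sent)
        assert distance_constraint(one, both, 4.0, sent)

    def test_large_beta_always_satisfiable(self):
        sent, both, one, _ = self._sentence5_graphs()
        assert distance_constraint(one, both, 100.0, sent)


class TestInformedEM:
    def test_huge_alpha_blocks_all_updates_and_equals_baseline(self):
        prepared = _prepared(seed=4, n_docs=4, span_inconsistency_rate=0.3)
        cfg = TrainingConfig(passes=6, init_rounds=2, alpha=1e9)
        em_models, adjusted = informed_em(prepared, cfg)
        base_models = train_baseline(prepared, cfg)
        assert adjusted.total_updates == 0
        for a, b in zip(em_models, base_models):
            assert a.node_weights == b.node_weights
            assert a.edge_weights == b.edge_weights

    def test_span_inconsistency_triggers_audited_updates(self):
        prepared = _prepared(seed=5, n_docs=10, span_inconsistency_rate=0.4)
        cfg = TrainingConfig(passes=8, init_rounds=3, alpha=0.0, beta=2.0)
        _models, adjusted = informed_em(prepared, cfg)
        assert adjusted.total_updates >= 1
        # audit every accepted update against the active constraints
        for ps, st in zip(adjusted.prepared, adjusted.states):
            for rec in st.history:
                assert rec.round_no > cfg.init_rounds
                assert basic_constraint(rec.new_graph, ps.gold_graph, ps.sentence)
                assert confidence_constraint(
                    rec.candidate_score, rec.current_score, cfg.alpha
                )
                assert distance_constraint(
                    rec.new_graph, rec.old_graph, cfg.beta, ps.sentence
                )

    def test_unconstrained_em_accepts_superset_of_updates(self):
        prepared1 = _prepared(seed=5, n_docs=10, span_inconsistency_rate=0.4)
        prepared2 = _prepared(seed=5, n_docs=10, span_inconsistency_rate=0.4)
        relaxed = TrainingConfig(passes=8, init_rounds=3, alpha=0.0, beta=1e9)
        strict = TrainingConfig(
            passes=8, init_rounds=3, alpha=0.5, beta=1.0, use_noc=True
        )
        _m1, adj_relaxed = informed_em(prepared1, relaxed)
        _m2, adj_strict = informed_em(prepared2, strict)
        assert adj_relaxed.total_updates >= adj_strict.total_updates

    def test_adjusted_graphs_preserve_gold_typed_structure(self):
        prepared = _prepared(seed=6, n_docs=8, span_inconsistency_rate=0.4)
        cfg = TrainingConfig(passes=8, init_rounds=3, alpha=0.0)
        _models, adjusted = informed_em(prepared, cfg)
        for ps, st in zip(adjusted.prepared, adjusted.states):
            assert basic_constraint(st.adjusted_graph, ps.gold_graph, ps.sentence)
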