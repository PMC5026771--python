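"""Assignment scoring, validity, and exact decoding vs. enumeration.

The enumeration oracle maximises the assignment score over all valid
label assignments by exhaustive search.  Validity couples each source
token only with its own out-edges, so the search space factorises per
source token; the oracle enumerates each token's full option table
(every node-label x edge-label combination) independently, and a second
joint oracle on two-token instances verifies the factorisation itself.
"""

from __future__ import annotations

import itertools
import random

import pytest

from iem.features import CandidateMask
from iem.scoring import (
    Assignment,
    EDGE_LABELS,
    INVALID,
    NEGATIVE,
    WeightVectors,
    assignment_score,
    decode,
    edge_score,
    is_valid,
    node_score,
    sparse_dot,
)
from iem.ontology import THEME
from conftest import make_sentence


def _sentence(n_tokens, protein_idx=()):
    words = [(f"w{i}", f"w{i}", "NN") for i in range(n_tokens)]
    return make_sentence(words, set(), proteins={i: f"T{i}" for i in protein_idx})


def _random_instance(rng, max_tokens=4, max_types=3, n_features=6):
    """Random mask, features and weights over a tiny sentence."""
    n_cand = rng.randint(1, max_tokens)
    n_prot = rng.randint(0, 1)
    n_tok = n_cand + n_prot
    sent = _sentence(n_tok, protein_idx=range(n_cand, n_tok))
    types = [f"Ty{k}" for k in range(rng.randint(1, max_types))]
    node_candidates = {
        i: frozenset(rng.sample(types, rng.randint(1, len(types))))
        for i in range(n_cand)
    }
    targets = set(range(n_tok))
    edges = frozenset(
        (i, j)
        for i in node_candidates
        for j in targets
        if i != j and rng.random() < 0.8
    )
    mask = CandidateMask(node_candidates, edges)

    def fv():
        return {f"f{k}": rng.uniform(-1, 1) for k in rng.sample(range(n_features), 3)}

    node_phis = {i: fv() for i in node_candidates}
    edge_phis = {e: fv() for e in edges}
    w = WeightVectors()
    for t in types:
        w.node_weights[t] = {f"f{k}": rng.uniform(-1, 1) for k in range(n_features)}
    for lab in EDGE_LABELS:
        w.edge_weights[lab] = {f"f{k}": rng.uniform(-1, 1) for k in range(n_features)}
    return sent, mask, node_phis, edge_phis, w


def enumerate_max_per_token(sent, mask, node_phis, edge_phis, w):
    """Independent oracle: per-source-token exhaustive option tables."""
    total = 0.0
    out_edges = {}
    for (i, j) in mask.edge_candidates:
        out_edges.setdefault(i, []).append(j)
    for i, types in sorted(mask.node_candidates.items()):
        types = sorted(types)
        targets = sorted(out_edges.get(i, []))
        best = None
        for node_combo in itertools.product([True, False], repeat=len(types)):
            for edge_combo in itertools.product(EDGE_LABELS, repeat=len(targets)):
                anchored = any(node_combo)
                has_theme = any(lab == THEME for lab in edge_combo)
                has_role = any(lab != NEGATIVE for lab in edge_combo)
                if anchored and not has_theme:
                    continue
                if has_role and not anchored:
                    continue
                s = sum(
                    node_score(i, e, pos, w, node_phis[i])
                    for e, pos in zip(types, node_combo)
                )
                s += sum(
                    edge_score(i, j, lab, w, edge_phis[(i, j)])
                    for j, lab in zip(targets, edge_combo)
                )
                best = s if best is None else max(best, s)
        total += best or 0.0
    return total


def enumerate_max_joint(sent, mask, node_phis, edge_phis, w):
    """Fully joint exhaustive oracle (small instances only)."""
    node_items = mask.node_items()
    edge_items = mask.edge_items()
    best = None
    for node_combo in itertools.product([True, False], repeat=len(node_items)):
        for edge_combo in itertools.product(EDGE_LABELS, repeat=len(edge_items)):
            a = Assignment(
                dict(zip(node_items, node_combo)),
                dict(zip(edge_items, edge_combo)),
            )
            s = assignment_score(a, w, node_phis, edge_phis)
            if s != INVALID and (best is None or s > best):
                best = s
    return best or 0.0


class TestScores:
    def test_zero_weights_zero_scores(self):
        w = WeightVectors()
        phi = {"a": 1.0}
        assert node_score(0, "Ty0", True, w, phi) == 0.0
        assert node_score(0, "Ty0", False, w, phi) == 0.0
        assert all(edge_score(0, 1, lab, w, phi) == 0.0 for lab in EDGE_LABELS)

    def test_sign_symmetry(self):
        w = WeightVectors()
        w.node_weights["Ty0"] = {"a": 1.5}
        phi = {"a": 1.0}
        assert node_score(0, "Ty0", True, w, phi) == 1.5
        assert node_score(0, "Ty0", False, w, phi) == -1.5

    def test_edge_single_feature_arithmetic(self):
        w = WeightVectors()
        w.edge_weights[THEME] = {"a": 2.0}
        assert edge_score(0, 1, THEME, w, {"a": 0.5}) == 1.0

    def test_unknown_edge_label_rejected(self):
        with pytest.raises(ValueError):
            edge_score(0, 1, "AGENT", WeightVectors(), {})

    def test_dot_matches_dense_oracle(self):
        rng = random.Random(5)
        for _ in range(20):
            w = {f"f{k}": rng.uniform(-1, 1) for k in rng.sample(range(10), 4)}
            phi = {f"f{k}": rng.uniform(-1, 1) for k in rng.sample(range(10), 4)}
            dense = sum(w.get(f"f{k}", 0) * phi.get(f"f{k}", 0) for k in range(10))
            assert sparse_dot(w, phi) == pytest.approx(dense)


class TestValidity:
    def _mask(self):
        return CandidateMask(
            {0: frozenset({"Ty0"}), 1: frozenset({"Ty0"})},
            frozenset({(0, 1), (1, 0)}),
        )

    def test_all_negative_valid(self):
        assert is_valid(Assignment.all_negative(self._mask()))

    def test_anchor_without_theme_invalid(self):
        a = Assignment.all_negative(self._mask())
        a.node_labels[(0, "Ty0")] = True
        assert not is_valid(a)
        assert assignment_score(a, WeightVectors(), {0: {}, 1: {}}, {(0, 1): {}, (1, 0): {}}) == INVALID

    def test_role_edge_from_non_anchor_invalid(self):
        a = Assignment.all_negative(self._mask())
        a.edge_labels[(0, 1)] = THEME
        assert not is_valid(a)

    def test_empty_mask_scores_zero(self):
        a = Assignment({}, {})
        assert assignment_score(a, WeightVectors(), {}, {}) == 0.0

    def test_two_node_manual_arithmetic(self):
        mask = self._mask()
        a = Assignment.all_negative(mask)
        a.node_labels[(0, "Ty0")] = True
        a.edge_labels[(0, 1)] = THEME
        w = WeightVectors()
        w.node_weights["Ty0"] = {"x": 1.0}
        w.edge_weights[THEME] = {"y": 2.0}
        w.edge_weights[NEGATIVE] = {"y": -0.5}
        node_phis = {0: {"x": 3.0}, 1: {"x": 1.0}}
        edge_phis = {(0, 1): {"y": 1.0}, (1, 0): {"y": 2.0}}
        # +3 (node 0 positive) -1 (node 1 negative) +2 (THEME) -1 (negative edge)
        assert assignment_score(a, w, node_phis, edge_phis) == pytest.approx(3.0)


class TestDecode:
    def test_zero_weights_all_negative(self):
        sent = _sentence(3, protein_idx=[2])
        mask = CandidateMask(
            {0: frozenset({"Ty0"}), 1: frozenset({"Ty0"})},
            frozenset({(0, 1), (0, 2), (1, 2)}),
        )
        node_phis = {0: {"a": 1.0}, 1: {"a": 1.0}}
        edge_phis = {e: {"a": 1.0} for e in mask.edge_candidates}
        a = decode(sent, WeightVectors(), mask, node_phis, edge_phis)
        assert not a.anchors() and not a.role_edges() and a.score == 0.0

    @pytest.mark.parametrize("seed", range(8))
    def test_matches_per_token_enumeration(self, seed):
        rng = random.Random(seed)
        for _ in range(10):
            sent, mask, node_phis, edge_phis, w = _random_instance(rng)
            a = decode(sent, w, mask, node_phis, edge_phis)
            oracle = enumerate_max_per_token(sent, mask, node_phis, edge_phis, w)
            assert a.score == pytest.approx(oracle)

    @pytest.mark.parametrize("seed", range(4))
    def test_matches_joint_enumeration_small(self, seed):
        rng = random.Random(100 + seed)
        for _ in range(8):
            sent, mask, node_phis, edge_phis, w = _random_instance(rng, max_tokens=2, max_types=2)
            a = decode(sent, w, mask, node_phis, edge_phis)
            oracle = enumerate_max_joint(sent, mask, node_phis, edge_phis, w)
            assert a.score == pytest.approx(oracle)

    def test_refinement_removes_edges_to_non_anchor_non_protein(self):
        # force a THEME edge to a non-anchor candidate and watch it vanish
        sent = _sentence(3, protein_idx=[2])
        mask = CandidateMask(
            {0: frozenset({"Ty0"}), 1: frozenset({"Ty0"})},
            frozenset({(0, 1), (0, 2), (1, 2)}),
        )
        w = WeightVectors()
        w.node_weights["Ty0"] = {"n0": 1.0, "n1": -1.0}
        w.edge_weights[THEME] = {"e01": 5.0, "e02": 1.0}
        node_phis = {0: {"n0": 1.0}, 1: {"n1": 1.0}}
        edge_phis = {(0, 1): {"e01": 1.0}, (0, 2): {"e02": 1.0}, (1, 2): {}}
        a = decode(sent, w, mask, node_phis, edge_phis)
        # token 1 is not an anchor, so (0,1) must be refined to negative;
        # (0,2) targets a protein and survives as the THEME edge
        assert a.edge_labels[(0, 1)] == NEGATIVE
        assert a.edge_labels[(0, 2)] == THEME
        assert is_valid(a)

    def test_refinement_cascade_demotes_anchor(self):
        # anchor 0's only THEME edge targets candidate 1 which stays
        # negative: refinement removes the edge, then demotes anchor 0
        sent = _sentence(2)
        mask = CandidateMask(
            {0: frozenset({"Ty0"}), 1: frozenset({"Ty0"})}, frozenset({(0, 1)})
        )
        w = WeightVectors()
        w.node_weights["Ty0"] = {"n0": 1.0, "n1": -1.0}
        w.edge_weights[THEME] = {"e": 1.0}
        node_phis = {0: {"n0": 1.0}, 1: {"n1": 1.0}}
        edge_phis = {(0, 1): {"e": 1.0}}
        a = decode(sent, w, mask, node_phis, edge_phis)
        assert not a.anchors() and not a.role_edges()

    def test_cycle_sets_no_events_flag(self):
        sent = _sentence(2)
        mask = CandidateMask(
            {0: frozenset({"Ty0"}), 1: frozenset({"Ty0"})},
            frozenset({(0, 1), (1, 0)}),
        )
        w = WeightVectors()
        w.node_weights["Ty0"] = {"n": 1.0}
        w.edge_weights[THEME] = {"e": 5.0}
        node_phis = {0: {"n": 1.0}, 1: {"n": 1.0}}
        edge_phis = {(0, 1): {"e": 1.0}, (1, 0): {"e": 1.0}}
        a = decode(sent, w, mask, node_phis, edge_phis)
        assert a.no_events

    def test_output_satisfies_validity_and_target_condition(self):
        rng = random.Random(42)
        for _ in range(30):
            sent, mask, node_phis, edge_phis, w = _random_instance(rng)
            a = decode(sent, w, mask, node_phis, edge_phis)
            assert is_valid(a)
            proteins = {t.index for t in sent.tokens if t.protein_id}
            if not a.no_events:
                for (i, j), lab in a.role_edges().items():
                    assert j in a.anchors() or j in proteins


class TestSerialisation:
    def test_weights_tsv_round_trip(self):
        w = WeightVectors()
        w.node_weights["Gene_expression"] = {"a": 0.125, "b": -3.5}
        w.edge_weights[THEME] = {"c": 1.0 / 3.0}
        again = WeightVectors.from_tsv(w.to_tsv())
        assert again.node_weights == w.node_weights
        assert again.edge_weights[THEME] == w.edge_weights[THEME]
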