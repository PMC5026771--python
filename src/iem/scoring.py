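"""Linear scoring of label assignments and exact decoding.

An assignment L labels every candidate (word, event type) pair positive
or negative and every candidate ordered word pair THEME, CAUSE or
negative.  Its score is the sum of per-node scores w_e·Φ(x_i) (sign
flipped for negative labels) and per-edge scores w_L·Φ(x_i, x_j), where
'negative' edges carry their own weight vector.  Assignments violating
either structural validity condition — every anchor has at least one
outgoing THEME edge; every role edge leaves an anchor — score -inf.

Decoding is exact and decomposes per source token (each token's label
options couple only with its own out-edges), followed by a refinement
pass enforcing the target-side condition (role edges must end at anchors
or proteins) and a cycle check.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import networkx as nx

from .features import CandidateMask, FeatureVector
from .ontology import CAUSE, THEME
from .standoff import Sentence

NEGATIVE = "negative"
EDGE_LABELS = (THEME, CAUSE, NEGATIVE)

INVALID = float("-inf")


def sparse_dot(w: Mapping[str, float], fv: FeatureVector) -> float:
    if len(w) < len(fv):
        return sum(v * fv.get(k, 0.0) for k, v in w.items())
    return sum(v * w.get(k, 0.0) for k, v in fv.items())


@dataclass
class WeightVectors:
    """The model M: one sparse weight vector per event type and edge label."""

    node_weights: dict[str, dict[str, float]] = field(default_factory=dict)
    edge_weights: dict[str, dict[str, float]] = field(
        default_factory=lambda: {lab: {} for lab in EDGE_LABELS}
    )

    def node_vec(self, event_type: str) -> dict[str, float]:
        return self.node_weights.setdefault(event_type, {})

    def edge_vec(self, label: str) -> dict[str, float]:
        if label not in EDGE_LABELS:
            raise ValueError(f"unknown edge label {label!r}")
        return self.edge_weights.setdefault(label, {})

    def copy(self) -> "WeightVectors":
        return WeightVectors(
            {e: dict(v) for e, v in self.node_weights.items()},
            {l: dict(v) for l, v in self.edge_weights.items()},
        )

    def add_scaled(self, other: "WeightVectors", scale: float) -> None:
        for e, vec in other.node_weights.items():
            tgt = self.node_vec(e)
            for k, v in vec.items():
                tgt[k] = tgt.get(k, 0.0) + scale * v
        for l, vec in other.edge_weights.items():
            tgt = self.edge_vec(l)
            for k, v in vec.items():
                tgt[k] = tgt.get(k, 0.0) + scale * v

    def scaled(self, scale: float) -> "WeightVectors":
        out = WeightVectors()
        out.add_scaled(self, scale)
        return out

    def norm_sq(self) -> float:
        return sum(
            v * v for vec in self.node_weights.values() for v in vec.values()
        ) + sum(v * v for vec in self.edge_weights.values() for v in vec.values())

    # -- serialisation: namespace<TAB>feature<TAB>weight -------------------
    def to_tsv(self) -> str:
        lines = ["#iem-model\tv1\t"]
        for e in sorted(self.node_weights):
            for k in sorted(self.node_weights[e]):
                lines.append(f"node:{e}\t{k}\t{self.node_weights[e][k]!r}")
        for l in sorted(self.edge_weights):
            for k in sorted(self.edge_weights[l]):
                lines.append(f"edge:{l}\t{k}\t{self.edge_weights[l][k]!r}")
        return "".join(line + "\n" for line in lines)

    @classmethod
    def from_tsv(cls, text: str) -> "WeightVectors":
        w = cls()
        for line in text.splitlines():
            if not line.strip() or line.startswith("#"):
                continue
            ns, feat, val = line.split("\t")
            kind, _, label = ns.partition(":")
            vec = w.node_vec(label) if kind == "node" else w.edge_vec(label)
            vec[feat] = float(val)
        return w

    def save(self, path: str | Path) -> None:
        Path(path).write_text(self.to_tsv())

    @classmethod
    def load(cls, path: str | Path) -> "WeightVectors":
        return cls.from_tsv(Path(path).read_text())


@dataclass
class Assignment:
    """One labeling of a sentence's candidate mask.

    ``node_labels[(i, e)]`` is True for positive; ``edge_labels[(i, j)]``
    is THEME, CAUSE or negative.  Defined exactly on the mask.
    """

    node_labels: dict[tuple[int, str], bool]
    edge_labels: dict[tuple[int, int], str]
    score: float = 0.0
    no_events: bool = False

    def anchors(self) -> set[int]:
        return {i for (i, _e), pos in self.node_labels.items() if pos}

    def positive_types(self, i: int) -> frozenset[str]:
        return frozenset(
            e for (k, e), pos in self.node_labels.items() if k == i and pos
        )

    def role_edges(self) -> dict[tuple[int, int], str]:
        return {k: l for k, l in self.edge_labels.items() if l != NEGATIVE}

    def labels_equal(self, other: "Assignment") -> bool:
        return (
            self.node_labels == other.node_labels
            and self.edge_labels == other.edge_labels
            and self.no_events == other.no_events
        )

    @classmethod
    def all_negative(cls, mask: CandidateMask) -> "Assignment":
        return cls(
            {key: False for key in mask.node_items()},
            {key: NEGATIVE for key in mask.edge_items()},
        )


def node_score(
    i: int, e: str, positive: bool, w: WeightVectors, phi: FeatureVector
) -> float:
    s = sparse_dot(w.node_weights.get(e, {}), phi)
    return s if positive else -s


def edge_score(
    i: int, j: int, label: str, w: WeightVectors, phi: FeatureVector
) -> float:
    if label not in EDGE_LABELS:
        raise ValueError(f"unknown edge label {label!r}")
    return sparse_dot(w.edge_weights.get(label, {}), phi)


def is_valid(a: Assignment) -> bool:
    """Both structural validity conditions of the model."""
    anchors = a.anchors()
    # condition 2: role edges come from anchors
    for (i, _j), label in a.edge_labels.items():
        if label != NEGATIVE and i not in anchors:
            return False
    # condition 1: anchors have >=1 outgoing THEME edge
    for i in anchors:
        if not any(
            label == THEME and s == i for (s, _j), label in a.edge_labels.items()
        ):
            return False
    return True


def assignment_score(
    a: Assignment,
    w: WeightVectors,
    node_phis: Mapping[int, FeatureVector],
    edge_phis: Mapping[tuple[int, int], FeatureVector],
) -> float:
    """Total score of *a*, or ``-inf`` (INVALID) when structurally invalid."""
    if not is_valid(a):
        return INVALID
    total = 0.0
    for (i, e), pos in a.node_labels.items():
        total += node_score(i, e, pos, w, node_phis[i])
    for (i, j), label in a.edge_labels.items():
        total += edge_score(i, j, label, w, edge_phis[(i, j)])
    return total


def decode(
    sentence: Sentence,
    w: WeightVectors,
    mask: CandidateMask,
    node_phis: Mapping[int, FeatureVector],
    edge_phis: Mapping[tuple[int, int], FeatureVector],
) -> Assignment:
    """Highest-scoring valid assignment, refined and cycle-checked.

    Pass 1 decides, independently per source token, between the non-anchor
    option (everything negative) and the best anchor option (each type
    takes its better label with at least one forced positive; each
    out-edge its best label with at least one forced THEME).  Ties resolve
    to negative.  Pass 2 relabels role edges ending at non-anchor,
    non-protein tokens as negative and demotes anchors that thereby lose
    their last THEME edge, iterated to a fixpoint.  Pass 3 sets the
    ``no_events`` flag when the surviving role-edge graph is cyclic.

    ``score`` on the result is the pass-1 (pre-refinement) optimum.
    """
    node_labels: dict[tuple[int, str], bool] = {}
    edge_labels: dict[tuple[int, int], str] = {}
    total = 0.0

    out_edges: dict[int, list[int]] = {}
    for (i, j) in mask.edge_candidates:
        out_edges.setdefault(i, []).append(j)

    for i in sorted(mask.node_candidates):
        types = sorted(mask.node_candidates[i])
        targets = sorted(out_edges.get(i, []))

        node_dots = {e: sparse_dot(w.node_weights.get(e, {}), node_phis[i]) for e in types}
        edge_dots = {
            j: {
                lab: sparse_dot(w.edge_weights.get(lab, {}), edge_phis[(i, j)])
                for lab in EDGE_LABELS
            }
            for j in targets
        }

        # non-anchor option
        non_anchor = -sum(node_dots.values()) + sum(
            edge_dots[j][NEGATIVE] for j in targets
        )

        # anchor option (requires at least one out-edge to carry THEME)
        anchor_score = None
        anchor_nodes: dict[str, bool] = {}
        anchor_edges: dict[int, str] = {}
        if targets:
            s = 0.0
            for e in types:
                # positive iff dot > -dot, i.e. dot > 0; ties to negative
                anchor_nodes[e] = node_dots[e] > 0.0
                s += node_dots[e] if anchor_nodes[e] else -node_dots[e]
            if not any(anchor_nodes.values()):
                # force the least costly type positive
                best_e = max(types, key=lambda e: (node_dots[e], e))
                anchor_nodes[best_e] = True
                s += 2.0 * node_dots[best_e]
            for j in targets:
                best_lab = max(EDGE_LABELS, key=lambda lab: edge_dots[j][lab])
                # ties to negative, then THEME before CAUSE
                top = edge_dots[j][best_lab]
                if edge_dots[j][NEGATIVE] == top:
                    best_lab = NEGATIVE
                elif edge_dots[j][THEME] == top:
                    best_lab = THEME
                anchor_edges[j] = best_lab
                s += edge_dots[j][best_lab]
            if THEME not in anchor_edges.values():
                # force the edge with the smallest THEME regret
                def regret(j: int) -> float:
                    return edge_dots[j][THEME] - edge_dots[j][anchor_edges[j]]

                best_j = max(targets, key=lambda j: (regret(j), -j))
                s += regret(best_j)
                anchor_edges[best_j] = THEME
            anchor_score = s

        if anchor_score is not None and anchor_score > non_anchor:
            total += anchor_score
            for e in types:
                node_labels[(i, e)] = anchor_nodes[e]
            for j in targets:
                edge_labels[(i, j)] = anchor_edges[j]
        else:
            total += non_anchor
            for e in types:
                node_labels[(i, e)] = False
            for j in targets:
                edge_labels[(i, j)] = NEGATIVE

    a = Assignment(node_labels, edge_labels, score=total)

    # pass 2: refinement to fixpoint
    protein_toks = {t.index for t in sentence.tokens if t.protein_id}
    for _ in range(len(sentence.tokens) + 1):
        changed = False
        anchors = a.anchors()
        for (i, j), label in list(a.edge_labels.items()):
            if label != NEGATIVE and j not in anchors and j not in protein_toks:
                a.edge_labels[(i, j)] = NEGATIVE
                changed = True
        anchors = a.anchors()
        for i in anchors:
            has_theme = any(
                lab == THEME and s == i for (s, _j), lab in a.edge_labels.items()
            )
            if not has_theme:
                for (k, e) in list(a.node_labels):
                    if k == i:
                        a.node_labels[(k, e)] = False
                for (s, j), lab in list(a.edge_labels.items()):
                    if s == i and lab != NEGATIVE:
                        a.edge_labels[(s, j)] = NEGATIVE
                changed = True
        if not changed:
            break

    # pass 3: cycle check on surviving role edges
    g = nx.DiGraph()
    g.add_edges_from(a.role_edges())
    if not nx.is_directed_acyclic_graph(g):
        a.no_events = True
    return a
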