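"""Sparse feature vectors for words and word pairs, and candidate masks.

Node features combine lexical identity (surface, baseform, POS), trigger-
lexicon reliability scores (real-valued), center-marked n-grams (n = 2-4)
of baseform:POS pairs with protein mentions rendered as ``PROTEIN``,
linear distances to proteins and to other lexicon-candidate words, and
governor/modifier dependency features.  Edge features add both endpoints'
node features (namespaced), the shortest dependency-path length, and
n-grams over three renderings of the path (token, dependency, and
interleaved token-dependency sequences).

Linear distances count word tokens only: punctuation tokens do not
occupy positions.

Candidate masks implement the efficiency filter: words with no lexicon
entry are fixed negative, and edges must start at a lexicon candidate
and end at a protein or another candidate.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import networkx as nx

from .lexicon import LexiconPair
from .ontology import GENE_EXPRESSION, POSITIVE_REGULATION, make_composite
from .standoff import DependencyGraph, Sentence, Token, word_rank

FeatureVector = dict[str, float]

BOUNDARY = "#B#"
PROTEIN_SYMBOL = "PROTEIN"


def token_distance(i: int, j: int, sentence: Sentence) -> int:
    """Linear distance in word tokens (punctuation does not count)."""
    toks = sentence.tokens
    return abs(word_rank(toks, i) - word_rank(toks, j))


def _lex_unit(tok: Token) -> str:
    if tok.protein_id:
        return PROTEIN_SYMBOL
    return f"{tok.baseform.lower()}:{tok.pos}"


def _add(fv: FeatureVector, name: str, value: float = 1.0) -> None:
    if value == 0.0:
        return
    prev = fv.get(name)
    if prev is None or value > prev:
        fv[name] = value


def _center_ngrams(fv: FeatureVector, i: int, tokens: Sequence[Token]) -> None:
    n_tok = len(tokens)

    def unit(k: int) -> str:
        if k < 0 or k >= n_tok:
            return BOUNDARY
        if k == i:
            return f"[{_lex_unit(tokens[k])}]"
        return _lex_unit(tokens[k])

    for n in range(2, 5):
        for start in range(i - n + 1, i + 1):
            gram = " ".join(unit(k) for k in range(start, start + n))
            _add(fv, f"ng{n}={gram}")


def _gov_mod_features(
    fv: FeatureVector, i: int, tokens: Sequence[Token], dg: DependencyGraph
) -> None:
    # both baseform- and surface-keyed renderings of the focus word are
    # emitted (the two coexist in practice for inflected forms)
    tok = tokens[i]
    self_units = {f"{tok.baseform.lower()}:{tok.pos}", f"{tok.surface}:{tok.pos}"}
    for g, rel in dg.governors_of(i):
        other = _lex_unit(tokens[g])
        for su in self_units:
            _add(fv, f"{su}-GOV({rel})-{other}")
    for d, rel in dg.dependents_of(i):
        other = _lex_unit(tokens[d])
        for su in self_units:
            _add(fv, f"{su}-MOD({rel})-{other}")


def node_feature_vector(
    i: int, sentence: Sentence, lex: LexiconPair | None = None
) -> FeatureVector:
    """Feature vector Φ(x_i) of one word."""
    tokens = sentence.tokens
    tok = tokens[i]
    fv: FeatureVector = {}
    _add(fv, f"w={tok.surface.lower()}")
    _add(fv, f"b={tok.baseform.lower()}")
    _add(fv, f"p={tok.pos}")
    if tok.protein_id:
        _add(fv, "is-protein")

    if lex is not None:
        for etype, r in lex.candidate_event_types(tok).items():
            _add(fv, f"R[{etype}]", r)

    _center_ngrams(fv, i, tokens)

    for other in tokens:
        if other.index == i:
            continue
        if other.protein_id:
            _add(fv, f"Protein-Distance:{token_distance(i, other.index, sentence)}")
        elif lex is not None:
            cand = lex.candidate_event_types(other)
            if cand:
                d = token_distance(i, other.index, sentence)
                _add(fv, f"Trigger-Distance:{d}", max(cand.values()))

    _gov_mod_features(fv, i, tokens, sentence.deps)
    return fv


# ---------------------------------------------------------------------------
# shortest dependency paths

def _undirected(dg: DependencyGraph) -> nx.Graph:
    g = nx.Graph()
    for gov, dep, rel in sorted(dg.edges):
        if g.has_edge(gov, dep):
            # parallel relations: keep the lexicographically smallest
            if rel < g[gov][dep]["rel"]:
                g[gov][dep].update(rel=rel, gov=gov)
        else:
            g.add_edge(gov, dep, rel=rel, gov=gov)
    return g


def shortest_dependency_path(
    dg: DependencyGraph, i: int, j: int
) -> list[tuple[int, str, str]] | None:
    """Shortest undirected path from *i* to *j* with per-step directions.

    Each step is ``(next_token, relation, direction)`` where direction is
    ``"GOV"`` when the step moves from a dependent to its governor and
    ``"MOD"`` when it moves from a governor to its dependent.  Ties break
    to the lexicographically smallest token-index sequence; ``None`` when
    disconnected.
    """
    if i == j:
        return []
    g = _undirected(dg)
    if i not in g or j not in g:
        return None
    try:
        paths = nx.all_shortest_paths(g, i, j)
        best = min(paths)
    except nx.NetworkXNoPath:
        return None
    steps: list[tuple[int, str, str]] = []
    for a, b in zip(best, best[1:]):
        data = g[a][b]
        direction = "GOV" if data["gov"] == b else "MOD"
        steps.append((b, data["rel"], direction))
    return steps


def _seq_ngrams(fv: FeatureVector, prefix: str, seq: list[str]) -> None:
    for n in range(2, 5):
        for start in range(0, len(seq) - n + 1):
            _add(fv, f"{prefix}{n}=" + " ".join(seq[start : start + n]))


def edge_feature_vector(
    i: int, j: int, sentence: Sentence, lex: LexiconPair | None = None
) -> FeatureVector:
    """Feature vector Φ(x_i, x_j) of an ordered word pair."""
    tokens = sentence.tokens
    fv: FeatureVector = {}
    for name, v in node_feature_vector(i, sentence, lex).items():
        _add(fv, f"SRC:{name}", v)
    for name, v in node_feature_vector(j, sentence, lex).items():
        _add(fv, f"TGT:{name}", v)

    path = shortest_dependency_path(sentence.deps, i, j)
    if path is None:
        return fv
    _add(fv, f"PathLen:{len(path)}")

    path_tokens = [i] + [t for t, _rel, _d in path]
    token_seq = [_lex_unit(tokens[k]) for k in path_tokens]
    dep_seq = [f"{d}({rel})" for _t, rel, d in path]

    _seq_ngrams(fv, "ts", token_seq)
    _seq_ngrams(fv, "ds", dep_seq)

    # token-dependency sequence: n counts tokens; connecting dependency
    # elements ride along inside the window
    for n in range(2, 5):
        for start in range(0, len(path_tokens) - n + 1):
            parts = [token_seq[start]]
            for k in range(start, start + n - 1):
                parts.append(dep_seq[k])
                parts.append(token_seq[k + 1])
            _add(fv, f"tds{n}=" + " ".join(parts))
    return fv


# ---------------------------------------------------------------------------
# candidate masks

@dataclass
class CandidateMask:
    """Admissible node labels and edges after the lexicon filter.

    ``node_candidates`` maps token index -> set of admissible labels
    (including the composite GE/PR label where both components match);
    ``edge_candidates`` is the set of admissible ordered pairs.
    """

    node_candidates: dict[int, frozenset[str]] = field(default_factory=dict)
    edge_candidates: frozenset[tuple[int, int]] = frozenset()

    def node_items(self) -> list[tuple[int, str]]:
        return sorted(
            (i, e) for i, types in self.node_candidates.items() for e in types
        )

    def edge_items(self) -> list[tuple[int, int]]:
        return sorted(self.edge_candidates)


def candidate_mask(sentence: Sentence, lex: LexiconPair) -> CandidateMask:
    """Build the candidate mask for one sentence.

    Node candidates are non-protein tokens matching at least one lexicon
    entry; edges run from a node candidate to a protein token or another
    node candidate (self-pairs excluded).
    """
    node_candidates: dict[int, frozenset[str]] = {}
    for tok in sentence.tokens:
        if tok.protein_id:
            continue
        types = set(lex.candidate_event_types(tok))
        if GENE_EXPRESSION in types and POSITIVE_REGULATION in types:
            types.add(make_composite(GENE_EXPRESSION, POSITIVE_REGULATION))
        if types:
            node_candidates[tok.index] = frozenset(types)

    protein_toks = {t.index for t in sentence.tokens if t.protein_id}
    edges = {
        (i, j)
        for i in node_candidates
        for j in (protein_toks | set(node_candidates))
        if i != j
    }
    return CandidateMask(node_candidates, frozenset(edges))
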