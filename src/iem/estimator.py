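"""Model/Results facade over the event-extraction pipeline.

:class:`EventExtractionModel` is constructed from an annotated corpus
(building the trigger lexicons and feature caches); ``fit`` trains by
the PA baseline or by informed EM and returns
:class:`EventExtractionResults`, which carries the per-pass averaged
weight vectors, the adjusted-corpus audit trail, model selection on a
held-out corpus, prediction, and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .evaluate import evaluate_corpus
from .features import candidate_mask, edge_feature_vector, node_feature_vector
from .graphs import graph_to_events
from .learning import (
    AdjustedCorpus,
    PreparedSentence,
    TrainingConfig,
    assignment_to_graph,
    informed_em,
    prepare_corpus,
    train_baseline,
)
from .lexicon import LexiconPair
from .scoring import WeightVectors, decode
from .standoff import Document, EventAnnotation


class EventExtractionModel:
    """A linear structured event-extraction model bound to a training corpus.

    Parameters
    ----------
    corpus:
        Training documents with gold standoff annotations and parses.
    config:
        Training hyper-parameters (passes, cost ratio, constraint
        constants alpha/beta, ...).
    lexicons:
        Pre-built trigger lexicons; derived from the corpus (pruned at
        1 %) when omitted.
    """

    def __init__(
        self,
        corpus: Sequence[Document],
        config: TrainingConfig | None = None,
        lexicons: LexiconPair | None = None,
    ) -> None:
        self.corpus = list(corpus)
        self.config = config or TrainingConfig()
        self.lexicons = lexicons or LexiconPair.build(self.corpus)
        self.prepared: list[PreparedSentence] = prepare_corpus(
            self.corpus, self.lexicons
        )

    @classmethod
    def from_directory(
        cls, path: str | Path, config: TrainingConfig | None = None
    ) -> "EventExtractionModel":
        from .standoff import read_corpus

        return cls(read_corpus(path), config=config)

    def fit(
        self,
        method: str = "informed_em",
        eval_corpus: Sequence[Document] | None = None,
    ) -> "EventExtractionResults":
        """Train and return a results object.

        ``method`` is ``"baseline"`` (cost-sensitive PA) or
        ``"informed_em"``.  When ``eval_corpus`` is given, per-pass
        models are scored on it (exact matching) and the best pass after
        the initialisation rounds is selected; otherwise the last pass.
        """
        if method == "baseline":
            models = train_baseline(self.prepared, self.config)
            adjusted = None
        elif method == "informed_em":
            models, adjusted = informed_em(self.prepared, self.config)
        else:
            raise ValueError(f"unknown method {method!r}")
        res = EventExtractionResults(self, method, models, adjusted)
        if eval_corpus is not None:
            res.select_best(eval_corpus)
        return res

    def predict_document(
        self, doc: Document, weights: WeightVectors
    ) -> list[EventAnnotation]:
        """Decode one document into event annotations."""
        events: list[EventAnnotation] = []
        for sent in doc.sentences:
            mask = candidate_mask(sent, self.lexicons)
            node_phis = {i: node_feature_vector(i, sent, self.lexicons) for i in mask.node_candidates}
            edge_phis = {
                (i, j): edge_feature_vector(i, j, sent, self.lexicons)
                for (i, j) in mask.edge_candidates
            }
            a = decode(sent, weights, mask, node_phis, edge_phis)
            if a.no_events:
                continue
            g = assignment_to_graph(a, sent.index)
            events.extend(graph_to_events(g, sent, id_prefix=f"P{sent.index}_"))
        return events


@dataclass
class EventExtractionResults:
    """Fitted models plus diagnostics.

    ``models[t]`` is the averaged weight vector after pass ``t+1``;
    ``adjusted`` (informed EM only) carries the adjusted annotation set
    and its update history.
    """

    model: EventExtractionModel
    method: str
    models: list[WeightVectors]
    adjusted: AdjustedCorpus | None = None
    best_pass: int | None = None
    pass_scores: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def weights(self) -> WeightVectors:
        """Selected (or final) averaged weight vector."""
        idx = self.best_pass if self.best_pass is not None else len(self.models) - 1
        return self.models[idx]

    def select_best(self, eval_corpus: Sequence[Document]) -> int:
        """Pick the best pass (> init rounds) by held-out exact-match F."""
        self.pass_scores = []
        for w in self.models:
            preds = {
                doc.id: self.model.predict_document(doc, w) for doc in eval_corpus
            }
            (r, p, f), _ = evaluate_corpus(eval_corpus, preds, mode="exact")
            self.pass_scores.append((r, p, f))
        start = min(self.model.config.init_rounds, len(self.models) - 1)
        self.best_pass = max(
            range(start, len(self.models)), key=lambda t: self.pass_scores[t]
        )
        return self.best_pass

    def predict(
        self, corpus: Iterable[Document]
    ) -> dict[str, list[EventAnnotation]]:
        w = self.weights
        return {doc.id: self.model.predict_document(doc, w) for doc in corpus}

    def score(
        self, corpus: Sequence[Document], mode: str = "exact"
    ) -> tuple[tuple[float, float, float], pd.DataFrame]:
        """(recall, precision, F1) and per-type table on a corpus."""
        return evaluate_corpus(corpus, self.predict(corpus), mode=mode)

    @property
    def update_counts(self) -> Mapping[int, int]:
        return dict(self.adjusted.updates_per_round) if self.adjusted else {}

    def summary(self) -> str:
        cfg = self.model.config
        lines = [
            "Event extraction model".center(58),
            "=" * 58,
            f"Method:              {self.method}",
            f"Training sentences:  {len(self.model.prepared)}",
            f"Passes:              {cfg.passes} (init {cfg.init_rounds})",
            f"FN cost ratio:       {cfg.fn_cost_ratio}",
        ]
        if self.method == "informed_em":
            lines += [
                f"alpha / beta / NOC:  {cfg.alpha} / {cfg.beta} / {cfg.use_noc}",
                f"Adjusted graphs:     {self.adjusted.total_updates if self.adjusted else 0} updates "
                f"{dict(self.update_counts)}",
            ]
        if self.pass_scores:
            lines.append("-" * 58)
            lines.append("pass   recall  precision   F1")
            for t, (r, p, f) in enumerate(self.pass_scores, 1):
                mark = " *" if self.best_pass == t - 1 else ""
                lines.append(f"{t:>4}   {r:6.3f}  {p:9.3f}  {f:5.3f}{mark}")
        lines.append("=" * 58)
        return "\n".join(lines)
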