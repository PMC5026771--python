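"""Event-level matching, recall/precision/F-score, the reconstruction
experiment, and the one-tailed paired t-test.

Matching modes:

* ``exact`` — event type, trigger span and the full recursive argument
  structure must agree;
* ``approximate-span`` — the predicted trigger span may lie anywhere
  within the gold span extended by one word on each side;
* ``approximate-recursive`` — nested event arguments match on type and
  THEME only.

Matching is greedy and one-to-one, in deterministic order (gold events
sorted by trigger offset then type).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import pandas as pd
from scipy import stats

from .graphs import AnchorRule, head_word, reconstruct_annotations
from .ontology import THEME
from .standoff import Document, EventAnnotation

MODES = ("exact", "approximate-span", "approximate-recursive")


@dataclass
class MatchResult:
    """One-to-one matching outcome for a document (or corpus totals)."""

    matched: int = 0
    gold: int = 0
    predicted: int = 0
    mode: str = "exact"
    pairs: list[tuple[str, str]] = field(default_factory=list)

    def __add__(self, other: "MatchResult") -> "MatchResult":
        return MatchResult(
            self.matched + other.matched,
            self.gold + other.gold,
            self.predicted + other.predicted,
            self.mode,
            self.pairs + other.pairs,
        )


def _extended_span(
    ev: EventAnnotation, doc: Document | None
) -> tuple[int, int]:
    """Gold trigger span extended one word to each side (approximate-span)."""
    start, end = ev.trigger_start, ev.trigger_end
    if doc is None:
        return start, end
    sent_idx = doc.sentence_of_span(start, end)
    if sent_idx is None:
        return start, end
    tokens = doc.sentences[sent_idx].tokens
    inside = [t.index for t in tokens if t.char_start < end and t.char_end > start]
    if not inside:
        return start, end
    lo = max(inside[0] - 1, 0)
    hi = min(inside[-1] + 1, len(tokens) - 1)
    return tokens[lo].char_start, tokens[hi].char_end


def _args_match(
    gold_args: Sequence[tuple[str, str]],
    pred_args: Sequence[tuple[str, str]],
    gold_index: Mapping[str, EventAnnotation],
    pred_index: Mapping[str, EventAnnotation],
    mode: str,
    doc: Document | None,
    nested: bool,
) -> bool:
    if len(gold_args) != len(pred_args):
        return False
    if not gold_args:
        return True
    # small argument lists: try every bijection
    for perm in itertools.permutations(range(len(pred_args))):
        ok = True
        for (g_role, g_target), k in zip(gold_args, perm):
            p_role, p_target = pred_args[k]
            if g_role != p_role:
                ok = False
                break
            g_is_event = g_target in gold_index
            p_is_event = p_target in pred_index
            if g_is_event != p_is_event:
                ok = False
                break
            if not g_is_event:
                if g_target != p_target:
                    ok = False
                    break
            else:
                if not _events_match(
                    gold_index[g_target],
                    pred_index[p_target],
                    gold_index,
                    pred_index,
                    mode,
                    doc,
                    nested=True,
                ):
                    ok = False
                    break
        if ok:
            return True
    return False


def _events_match(
    gold: EventAnnotation,
    pred: EventAnnotation,
    gold_index: Mapping[str, EventAnnotation],
    pred_index: Mapping[str, EventAnnotation],
    mode: str,
    doc: Document | None,
    nested: bool = False,
) -> bool:
    if gold.event_type != pred.event_type:
        return False
    if mode == "approximate-recursive" and nested:
        # nested arguments: type + THEME only
        g_themes = [t for r, t in gold.args if r == THEME]
        p_themes = [t for r, t in pred.args if r == THEME]
        return _args_match(
            [(THEME, t) for t in g_themes],
            [(THEME, t) for t in p_themes],
            gold_index,
            pred_index,
            mode,
            doc,
            nested,
        )
    if mode == "approximate-span":
        lo, hi = _extended_span(gold, doc)
        if not (lo <= pred.trigger_start and pred.trigger_end <= hi):
            return False
    else:
        if (gold.trigger_start, gold.trigger_end) != (
            pred.trigger_start,
            pred.trigger_end,
        ):
            return False
    return _args_match(gold.args, pred.args, gold_index, pred_index, mode, doc, nested)


def match_events(
    gold: Iterable[EventAnnotation],
    pred: Iterable[EventAnnotation],
    mode: str = "exact",
    doc: Document | None = None,
) -> MatchResult:
    """Greedy one-to-one matching of predicted against gold events."""
    if mode not in MODES:
        raise ValueError(f"unknown mode {mode!r}; expected one of {MODES}")
    gold = sorted(gold, key=lambda e: (e.trigger_start, e.trigger_end, e.event_type, e.id))
    pred = sorted(pred, key=lambda e: (e.trigger_start, e.trigger_end, e.event_type, e.id))
    gold_index = {e.id: e for e in gold}
    pred_index = {e.id: e for e in pred}
    result = MatchResult(gold=len(gold), predicted=len(pred), mode=mode)
    used: set[str] = set()
    for g in gold:
        for p in pred:
            if p.id in used:
                continue
            if _events_match(g, p, gold_index, pred_index, mode, doc):
                used.add(p.id)
                result.matched += 1
                result.pairs.append((g.id, p.id))
                break
    return result


def prf(m: MatchResult) -> tuple[float, float, float]:
    """(recall, precision, F1); 0/0 ratios are 1.0, F1 is 0 when r+p = 0."""
    r = m.matched / m.gold if m.gold else 1.0
    p = m.matched / m.predicted if m.predicted else 1.0
    f = 2 * r * p / (r + p) if (r + p) else 0.0
    return r, p, f


def prf_table(results_by_type: Mapping[str, MatchResult]) -> pd.DataFrame:
    """R/P/F table per event type plus an overall row."""
    rows = {}
    overall = MatchResult()
    for etype in sorted(results_by_type):
        m = results_by_type[etype]
        overall += m
        rows[etype] = (*prf(m), m.gold, m.predicted, m.matched)
    rows["OVERALL"] = (*prf(overall), overall.gold, overall.predicted, overall.matched)
    return pd.DataFrame.from_dict(
        rows,
        orient="index",
        columns=["recall", "precision", "f1", "gold", "predicted", "matched"],
    )


def evaluate_corpus(
    gold_docs: Iterable[Document],
    predictions: Mapping[str, Iterable[EventAnnotation]],
    mode: str = "exact",
) -> tuple[tuple[float, float, float], pd.DataFrame]:
    """Corpus-level R/P/F plus a per-type breakdown.

    Per-type attribution: an event counts toward its own type's bucket
    only; matched pairs are split by gold event type.
    """
    by_type: dict[str, MatchResult] = {}
    for doc in gold_docs:
        gold = list(doc.events.values())
        pred = list(predictions.get(doc.id, []))
        m = match_events(gold, pred, mode, doc)
        matched_gold_ids = {g for g, _p in m.pairs}
        matched_pred_ids = {p for _g, p in m.pairs}
        gold_by_id = {e.id: e for e in gold}
        types = {e.event_type for e in gold} | {e.event_type for e in pred}
        for etype in types:
            part = by_type.setdefault(etype, MatchResult(mode=mode))
            part.gold += sum(1 for e in gold if e.event_type == etype)
            part.predicted += sum(1 for e in pred if e.event_type == etype)
            part.matched += sum(
                1 for g in matched_gold_ids if gold_by_id[g].event_type == etype
            )
        del matched_pred_ids
    overall = MatchResult(mode=mode)
    for part in by_type.values():
        overall += part
    return prf(overall), prf_table(by_type)


def reconstruction_f1(
    corpus: Sequence[Document],
    use_merged: bool = True,
    anchor_rule: AnchorRule = head_word,
) -> tuple[tuple[float, float, float], pd.DataFrame]:
    """F-score of gold annotations round-tripped through the graphs.

    Events that cannot be encoded in the graph representation cannot
    survive reconstruction; merged events recover GE/PR trigger-sharing
    loops.  Exact matching.
    """
    recon = reconstruct_annotations(corpus, use_merged, anchor_rule)
    return evaluate_corpus(corpus, recon, mode="exact")


def paired_one_tailed_ttest(
    scores_a: Sequence[float], scores_b: Sequence[float]
) -> float:
    """p-value of the one-tailed paired t-test for H1: mean(a − b) > 0.

    Degenerate cases: all differences zero → 0.5 (t = 0 boundary); zero
    variance with nonzero mean → 0 if the mean is positive else 1.
    """
    if len(scores_a) != len(scores_b) or len(scores_a) < 2:
        raise ValueError("need two equal-length sequences of length >= 2")
    diffs = [a - b for a, b in zip(scores_a, scores_b)]
    mean = sum(diffs) / len(diffs)
    if all(d == diffs[0] for d in diffs):
        if mean == 0.0:
            return 0.5
        return 0.0 if mean > 0 else 1.0
    return float(stats.ttest_rel(scores_a, scores_b, alternative="greater").pvalue)
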