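"""Per-event-type trigger lexicons with reliability scores.

Constituent words of annotated event triggers are scanned into the
lexicon of the trigger's event type; hyphenated words contribute both
their components and the original word.  Each entry ``w`` in the lexicon
of type ``e`` carries the reliability score

    R_{w,e} = C_{w,e} / C_w

where ``C_{w,e}`` counts occurrences of ``w`` within triggers of type
``e`` and ``C_w`` counts all occurrences of ``w`` in the corpus.  Entries
with reliability below 1 % are pruned.  A stemmed variant of every
lexicon (Porter stems) is built alongside and consulted jointly during
candidate lookup.

Entries are lowercase; lookups derive entries from a token's surface,
baseform and hyphen components (stems thereof for the stemmed lexicon).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

from ._porter import stem as porter_stem
from .standoff import Document, Token, tokenize


def hyphen_expand(word: str) -> list[str]:
    """The word itself plus its hyphen components (if hyphenated)."""
    out = [word]
    if "-" in word:
        out.extend(c for c in word.split("-") if c)
    return out


def derive_entries(word: str, stemmed: bool) -> set[str]:
    """Lexicon entries derivable from one word occurrence."""
    entries = set(hyphen_expand(word.lower()))
    if stemmed:
        entries = {porter_stem(e) for e in entries}
    return entries


@dataclass
class TriggerLexicon:
    """Counts and reliability scores for one lexicon family.

    ``counts[e][w]`` is C_{w,e}; ``totals[w]`` is C_w.
    """

    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    totals: dict[str, int] = field(default_factory=dict)
    stemmed: bool = False

    def reliability(self, entry: str, event_type: str) -> float:
        c_we = self.counts.get(event_type, {}).get(entry, 0)
        if not c_we:
            return 0.0
        return c_we / self.totals[entry]

    def entries(self, event_type: str) -> Mapping[str, int]:
        return self.counts.get(event_type, {})

    def event_types(self) -> list[str]:
        return sorted(self.counts)

    def prune(self, threshold: float = 0.01) -> "TriggerLexicon":
        """Drop entries with reliability strictly below *threshold*.

        ``C_w`` totals are untouched; pruning is idempotent and monotone
        (raising the threshold never adds entries back).
        """
        if not 0.0 <= threshold <= 1.0:
            raise ValueError(f"threshold must lie in [0, 1], got {threshold}")
        pruned = {
            e: {
                w: c
                for w, c in by_entry.items()
                if self.reliability(w, e) >= threshold
            }
            for e, by_entry in self.counts.items()
        }
        pruned = {e: d for e, d in pruned.items() if d}
        return TriggerLexicon(pruned, dict(self.totals), self.stemmed)

    # -- serialisation -----------------------------------------------------
    def to_tsv(self) -> str:
        lines = []
        for e in sorted(self.counts):
            for w in sorted(self.counts[e]):
                c_we = self.counts[e][w]
                c_w = self.totals.get(w, c_we)
                lines.append(f"{e}\t{w}\t{c_we}\t{c_w}\t{c_we / c_w:.6g}")
        return "".join(line + "\n" for line in lines)

    @classmethod
    def from_tsv(cls, text: str, stemmed: bool = False) -> "TriggerLexicon":
        lex = cls(stemmed=stemmed)
        for line in text.splitlines():
            if not line.strip():
                continue
            e, w, c_we, c_w, _r = line.split("\t")
            lex.counts.setdefault(e, {})[w] = int(c_we)
            lex.totals[w] = int(c_w)
        return lex


def _trigger_words(trigger_text: str) -> list[str]:
    return [surface for surface, _s, _e in tokenize(trigger_text)]


def build_trigger_lexicons(
    corpus: Iterable[Document], stemmed: bool = False
) -> TriggerLexicon:
    """Scan gold triggers of *corpus* into a :class:`TriggerLexicon`.

    Every constituent word of every annotated trigger occurrence
    contributes to C_{w,e}; C_w is counted over all token occurrences in
    the corpus (plus trigger words, for robustness when lexical analyses
    are absent).
    """
    lex = TriggerLexicon(stemmed=stemmed)
    docs = list(corpus)
    for doc in docs:
        # C_{w,e}: constituent words of each trigger occurrence
        seen_triggers: set[tuple[str, int, int]] = set()
        for ev in doc.events.values():
            key = (ev.event_type, ev.trigger_start, ev.trigger_end)
            if key in seen_triggers:
                continue  # two events sharing one trigger: count once
            seen_triggers.add(key)
            for word in _trigger_words(ev.trigger_text):
                for entry in derive_entries(word, stemmed):
                    by_entry = lex.counts.setdefault(ev.event_type, {})
                    by_entry[entry] = by_entry.get(entry, 0) + 1
        # C_w: all token occurrences
        for sent in doc.sentences:
            for tok in sent.tokens:
                for entry in derive_entries(tok.surface, stemmed):
                    lex.totals[entry] = lex.totals.get(entry, 0) + 1
        if not doc.sentences:
            # no lexical analyses attached: count the raw text
            for surface, _s, _e in tokenize(doc.text):
                for entry in derive_entries(surface, stemmed):
                    lex.totals[entry] = lex.totals.get(entry, 0) + 1
    # guarantee C_{w,e} <= C_w even for degenerate fixtures
    for e, by_entry in lex.counts.items():
        for w, c in by_entry.items():
            if lex.totals.get(w, 0) < c:
                lex.totals[w] = c
    return lex


@dataclass
class LexiconPair:
    """Unstemmed + stemmed lexicons consulted jointly (max-pooled)."""

    plain: TriggerLexicon
    stemmed: TriggerLexicon

    @classmethod
    def build(
        cls, corpus: Iterable[Document], prune_threshold: float = 0.01
    ) -> "LexiconPair":
        docs = list(corpus)
        return cls(
            build_trigger_lexicons(docs, stemmed=False).prune(prune_threshold),
            build_trigger_lexicons(docs, stemmed=True).prune(prune_threshold),
        )

    def candidate_event_types(self, token: Token) -> dict[str, float]:
        return candidate_event_types(token, self.plain, self.stemmed)

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        (directory / "lexicon.tsv").write_text(self.plain.to_tsv())
        (directory / "lexicon.stemmed.tsv").write_text(self.stemmed.to_tsv())

    @classmethod
    def load(cls, directory: str | Path) -> "LexiconPair":
        directory = Path(directory)
        return cls(
            TriggerLexicon.from_tsv((directory / "lexicon.tsv").read_text()),
            TriggerLexicon.from_tsv(
                (directory / "lexicon.stemmed.tsv").read_text(), stemmed=True
            ),
        )


def candidate_event_types(
    token: Token, lex: TriggerLexicon, stemmed_lex: TriggerLexicon | None = None
) -> dict[str, float]:
    """Event types for which *token* matches a lexicon entry.

    Returns ``{event_type: max reliability}`` over all entries derivable
    from the token (surface, baseform, hyphen components; Porter stems
    for the stemmed lexicon).  Empty when nothing matches.
    """
    words = {token.surface.lower(), token.baseform.lower()}
    out: dict[str, float] = {}
    for lx in (lex, stemmed_lex):
        if lx is None:
            continue
        entries: set[str] = set()
        for w in words:
            entries |= derive_entries(w, lx.stemmed)
        for e in lx.counts:
            for entry in entries:
                r = lx.reliability(entry, e)
                if r > 0.0 and r > out.get(e, 0.0):
                    out[e] = r
    return out
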