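"""BioNLP'09-style standoff annotation I/O and token-level plumbing.

A document is distributed across several plain-text files sharing a stem:

* ``<id>.txt`` — the document text;
* ``<id>.a1``  — protein mentions (``T`` lines, character offsets);
* ``<id>.a2``  — event triggers (``T`` lines) and events (``E`` lines);
* ``<id>.tok`` — per-sentence lexical analyses, one token per line as
  ``surface<TAB>baseform<TAB>POS``, sentences separated by blank lines;
* ``<id>.dep`` — per-sentence basic Stanford dependencies in
  ``rel(gov-i, dep-j)`` line format (1-based indices), blank-line separated.

Character offsets are 0-based half-open; token indices 0-based internally.
Multi-word protein mentions are normalised into single tokens with their
dependency relations redirected (see :func:`merge_protein_tokens`).
"""

from __future__ import annotations

import re
import string
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from .ontology import THEME, CAUSE

_PUNCT = set(string.punctuation)


class StandoffParseError(ValueError):
    """A malformed standoff or dependency line (names the line number)."""


class AlignmentError(ValueError):
    """A mention span that does not align with token boundaries."""


@dataclass(frozen=True)
class Token:
    """One token of a sentence; carries the lexical analysis."""

    index: int
    surface: str
    baseform: str
    pos: str
    char_start: int
    char_end: int
    protein_id: str | None = None

    @property
    def is_punct(self) -> bool:
        return bool(self.surface) and all(c in _PUNCT for c in self.surface)


@dataclass(frozen=True)
class ProteinMention:
    id: str
    char_start: int
    char_end: int
    text: str


@dataclass(frozen=True)
class DependencyGraph:
    """Set of labeled directed dependency edges (governor, dependent, relation)."""

    edges: frozenset[tuple[int, int, str]] = frozenset()

    def governors_of(self, i: int) -> list[tuple[int, str]]:
        return sorted((g, rel) for g, d, rel in self.edges if d == i)

    def dependents_of(self, i: int) -> list[tuple[int, str]]:
        return sorted((d, rel) for g, d, rel in self.edges if g == i)


@dataclass(frozen=True)
class EventAnnotation:
    """One event: type, trigger span, and role-labeled arguments.

    ``args`` entries are ``(role, target_id)`` where the target id is a
    protein mention id (``T..``) or another event id (``E..``).
    """

    id: str
    event_type: str
    trigger_start: int
    trigger_end: int
    trigger_text: str
    args: tuple[tuple[str, str], ...]

    def themes(self) -> tuple[str, ...]:
        return tuple(t for r, t in self.args if r == THEME)

    def causes(self) -> tuple[str, ...]:
        return tuple(t for r, t in self.args if r == CAUSE)


@dataclass
class Sentence:
    tokens: list[Token]
    deps: DependencyGraph
    index: int = 0

    @property
    def char_start(self) -> int:
        return self.tokens[0].char_start if self.tokens else 0

    @property
    def char_end(self) -> int:
        return self.tokens[-1].char_end if self.tokens else 0


@dataclass
class Document:
    id: str
    text: str
    sentences: list[Sentence] = field(default_factory=list)
    proteins: dict[str, ProteinMention] = field(default_factory=dict)
    events: dict[str, EventAnnotation] = field(default_factory=dict)

    def sentence_of_span(self, start: int, end: int) -> int | None:
        """Index of the sentence containing the character span, if any."""
        for s in self.sentences:
            if s.tokens and s.char_start <= start and end <= s.char_end:
                return s.index
        return None

    def token_of_protein(self, sent_idx: int, protein_id: str) -> int | None:
        for tok in self.sentences[sent_idx].tokens:
            if tok.protein_id == protein_id:
                return tok.index
        return None


# ---------------------------------------------------------------------------
# tokenisation (used by the synthetic generator and fixtures)

_TOKEN_RE = re.compile(r"[^\W_]+(?:[-'][^\W_]+)*|[^\w\s]")


def tokenize(text: str, offset: int = 0) -> list[tuple[str, int, int]]:
    """Whitespace/punctuation tokenizer: ``(surface, char_start, char_end)``.

    Punctuation is split off as separate tokens; word-internal hyphens and
    apostrophes are kept (``IFNgamma-induced`` stays one token).
    """
    return [
        (m.group(0), offset + m.start(), offset + m.end())
        for m in _TOKEN_RE.finditer(text)
    ]


def word_rank(tokens: Sequence[Token], i: int) -> int:
    """Position of token *i* counting word (non-punctuation) tokens only."""
    return sum(1 for t in tokens[:i] if not t.is_punct)


# ---------------------------------------------------------------------------
# standoff parsing

_T_LINE = re.compile(r"^(T\d+)\t(\S+) (\d+) (\d+)\t(.*)$")
_E_LINE = re.compile(r"^(E\d+)\t(\S+):(T\d+)((?: \S+:\S+)*)\s*$")
_ROLE_SUFFIX = re.compile(r"\d+$")


def _normalise_role(role: str) -> str:
    base = _ROLE_SUFFIX.sub("", role).upper()
    if base not in (THEME, CAUSE):
        raise StandoffParseError(f"unsupported role {role!r}")
    return base


def read_standoff_document(
    doc_id: str, txt: str, a1: str, a2: str = ""
) -> Document:
    """Parse ``.txt``/``.a1``/``.a2`` contents into a :class:`Document`.

    Raises :class:`StandoffParseError` naming the offending line on
    malformed input or dangling event references.
    """
    doc = Document(id=doc_id, text=txt)
    triggers: dict[str, tuple[str, int, int, str]] = {}

    for lineno, line in enumerate(a1.splitlines(), 1):
        if not line.strip():
            continue
        m = _T_LINE.match(line)
        if not m:
            raise StandoffParseError(f"{doc_id}.a1:{lineno}: malformed T line: {line!r}")
        tid, _etype, start, end, text = m.groups()
        start, end = int(start), int(end)
        if txt[start:end] != text:
            raise StandoffParseError(
                f"{doc_id}.a1:{lineno}: text {text!r} != document span {txt[start:end]!r}"
            )
        doc.proteins[tid] = ProteinMention(tid, start, end, text)

    event_lines: list[tuple[int, str]] = []
    for lineno, line in enumerate(a2.splitlines(), 1):
        if not line.strip():
            continue
        if line.startswith("T"):
            m = _T_LINE.match(line)
            if not m:
                raise StandoffParseError(
                    f"{doc_id}.a2:{lineno}: malformed T line: {line!r}"
                )
            tid, etype, start, end, text = m.groups()
            triggers[tid] = (etype, int(start), int(end), text)
        elif line.startswith("E"):
            event_lines.append((lineno, line))
        elif line.startswith("M"):
            continue  # Task-1 only: modification lines ignored
        else:
            raise StandoffParseError(f"{doc_id}.a2:{lineno}: unrecognised line: {line!r}")

    for lineno, line in event_lines:
        m = _E_LINE.match(line)
        if not m:
            raise StandoffParseError(f"{doc_id}.a2:{lineno}: malformed E line: {line!r}")
        eid, etype, trig_id, rest = m.groups()
        if trig_id not in triggers:
            raise StandoffParseError(
                f"{doc_id}.a2:{lineno}: event {eid} references unknown trigger {trig_id}"
            )
        t_etype, t_start, t_end, t_text = triggers[trig_id]
        if t_etype != etype:
            raise StandoffParseError(
                f"{doc_id}.a2:{lineno}: event type {etype} != trigger type {t_etype}"
            )
        args = []
        for part in rest.split():
            role, _, target = part.partition(":")
            args.append((_normalise_role(role), target))
        doc.events[eid] = EventAnnotation(
            eid, etype, t_start, t_end, t_text, tuple(args)
        )

    # resolve references
    for eid, ev in doc.events.items():
        for role, target in ev.args:
            if target.startswith("T"):
                if target not in doc.proteins:
                    raise StandoffParseError(
                        f"{doc_id}.a2: event {eid}: dangling protein reference {target}"
                    )
            elif target.startswith("E"):
                if target not in doc.events:
                    raise StandoffParseError(
                        f"{doc_id}.a2: event {eid}: dangling event reference {target}"
                    )
            else:
                raise StandoffParseError(
                    f"{doc_id}.a2: event {eid}: unresolvable argument {target}"
                )
    return doc


def write_a2(doc: Document, events: Iterable[EventAnnotation] | None = None) -> str:
    """Serialise events back to ``.a2`` text (trigger T lines + E lines).

    Ids are re-assigned densely; reading the output back reproduces the
    same event structure up to id renaming.  An event with no THEME is a
    contract violation and raises ``ValueError``.
    """
    evs = sorted(
        doc.events.values() if events is None else events,
        key=lambda e: (e.trigger_start, e.trigger_end, e.event_type, e.id),
    )
    for ev in evs:
        if not ev.themes():
            raise ValueError(f"event {ev.id} has no THEME argument")

    trigger_ids: dict[tuple[str, int, int], str] = {}
    lines: list[str] = []
    next_t = max(
        (int(p[1:]) for p in doc.proteins if p[1:].isdigit()), default=0
    ) + 1
    for ev in evs:
        key = (ev.event_type, ev.trigger_start, ev.trigger_end)
        if key not in trigger_ids:
            tid = f"T{next_t}"
            next_t += 1
            trigger_ids[key] = tid
            lines.append(
                f"{tid}\t{ev.event_type} {ev.trigger_start} {ev.trigger_end}\t{ev.trigger_text}"
            )

    new_eid = {ev.id: f"E{n}" for n, ev in enumerate(evs, 1)}
    for ev in evs:
        parts = [f"{new_eid[ev.id]}\t{ev.event_type}:{trigger_ids[(ev.event_type, ev.trigger_start, ev.trigger_end)]}"]
        theme_n = 0
        for role, target in ev.args:
            mapped = new_eid.get(target, target)
            if role == THEME:
                theme_n += 1
                label = "Theme" if theme_n == 1 else f"Theme{theme_n}"
            else:
                label = "Cause"
            parts.append(f"{label}:{mapped}")
        lines.append(parts[0] + (" " + " ".join(parts[1:]) if parts[1:] else ""))
    return "".join(line + "\n" for line in lines)


# ---------------------------------------------------------------------------
# dependency parses

_DEP_LINE = re.compile(r"^\s*([^\s(]+)\(\s*(.+?)-(\d+)\s*,\s*(.+?)-(\d+)\s*\)\s*$")


def read_dependency_parse(lines: str, tokens: Sequence[Token]) -> DependencyGraph:
    """Parse ``rel(gov-i, dep-j)`` lines (1-based) into 0-based edges.

    Relation labels are case-normalised to lowercase; duplicated lines
    collapse to one edge (set semantics).
    """
    edges: set[tuple[int, int, str]] = set()
    n = len(tokens)
    for lineno, line in enumerate(lines.splitlines(), 1):
        if not line.strip():
            continue
        m = _DEP_LINE.match(line)
        if not m:
            raise StandoffParseError(f"dep:{lineno}: malformed line: {line!r}")
        rel, _gov_w, gi, _dep_w, di = m.groups()
        gi, di = int(gi) - 1, int(di) - 1
        if not (0 <= gi < n and 0 <= di < n):
            raise StandoffParseError(
                f"dep:{lineno}: token index out of range in {line!r} (sentence has {n} tokens)"
            )
        edges.add((gi, di, rel.lower()))
    return DependencyGraph(frozenset(edges))


def write_dependency_parse(sentence: Sentence) -> str:
    """Inverse of :func:`read_dependency_parse` (1-based indices)."""
    out = []
    for g, d, rel in sorted(sentence.deps.edges):
        out.append(
            f"{rel}({sentence.tokens[g].surface}-{g + 1}, {sentence.tokens[d].surface}-{d + 1})"
        )
    return "".join(line + "\n" for line in out)


# ---------------------------------------------------------------------------
# protein-token merging

def merge_protein_tokens(
    tokens: Sequence[Token],
    dg: DependencyGraph,
    mentions: Iterable[ProteinMention],
    snap: bool = False,
) -> tuple[list[Token], DependencyGraph]:
    """Combine multi-word protein mentions into single tokens.

    Edges internal to a mention are dropped; edges crossing the mention
    boundary are redirected to the merged token; token indices are
    recomputed.  A mention not aligned to token boundaries raises
    :class:`AlignmentError` unless ``snap`` is set, in which case the
    mention is snapped outward to the covering tokens.
    """
    runs: list[tuple[int, int, ProteinMention]] = []  # [start_tok, end_tok) per mention
    for m in sorted(mentions, key=lambda m: (m.char_start, m.char_end)):
        covered = [
            t.index
            for t in tokens
            if t.char_start < m.char_end and t.char_end > m.char_start
        ]
        if not covered:
            raise AlignmentError(
                f"mention {m.id} [{m.char_start},{m.char_end}) covers no token"
            )
        lo, hi = covered[0], covered[-1] + 1
        if not snap and (
            tokens[lo].char_start != m.char_start or tokens[hi - 1].char_end != m.char_end
        ):
            raise AlignmentError(
                f"mention {m.id} [{m.char_start},{m.char_end}) not aligned to token "
                f"boundaries [{tokens[lo].char_start},{tokens[hi - 1].char_end})"
            )
        runs.append((lo, hi, m))

    for (lo1, hi1, m1), (lo2, hi2, m2) in zip(runs, runs[1:]):
        if hi1 > lo2:
            raise AlignmentError(f"mentions {m1.id} and {m2.id} overlap")

    old_to_new: dict[int, int] = {}
    new_tokens: list[Token] = []
    run_iter = iter(runs)
    cur = next(run_iter, None)
    i = 0
    while i < len(tokens):
        if cur and i == cur[0]:
            lo, hi, m = cur
            merged = Token(
                index=len(new_tokens),
                surface=m.text,
                baseform=m.text.lower(),
                pos="NN",
                char_start=tokens[lo].char_start,
                char_end=tokens[hi - 1].char_end,
                protein_id=m.id,
            )
            for j in range(lo, hi):
                old_to_new[j] = merged.index
            new_tokens.append(merged)
            i = hi
            cur = next(run_iter, None)
        else:
            old_to_new[i] = len(new_tokens)
            new_tokens.append(replace(tokens[i], index=len(new_tokens)))
            i += 1

    new_edges: set[tuple[int, int, str]] = set()
    for g, d, rel in dg.edges:
        ng, nd = old_to_new[g], old_to_new[d]
        if ng != nd:
            new_edges.add((ng, nd, rel))
        elif g == d:
            new_edges.add((ng, nd, rel))  # pre-existing self-loop kept verbatim
        # edges collapsing inside one mention are dropped
    return new_tokens, DependencyGraph(frozenset(new_edges))


# ---------------------------------------------------------------------------
# corpus directory I/O

def _split_blocks(text: str) -> list[list[str]]:
    blocks: list[list[str]] = [[]]
    for line in text.splitlines():
        if line.strip():
            blocks[-1].append(line)
        elif blocks[-1]:
            blocks.append([])
    if blocks and not blocks[-1]:
        blocks.pop()
    return blocks


def attach_sentences(doc: Document, tok_text: str, dep_text: str) -> None:
    """Attach lexical analyses and parses, then merge protein mentions.

    Token character offsets are recovered by left-to-right alignment of
    surfaces against the document text.
    """
    tok_blocks = _split_blocks(tok_text)
    dep_blocks = _split_blocks(dep_text)
    if len(dep_blocks) < len(tok_blocks):
        dep_blocks = dep_blocks + [[]] * (len(tok_blocks) - len(dep_blocks))
    if len(dep_blocks) != len(tok_blocks):
        raise StandoffParseError(
            f"{doc.id}: {len(tok_blocks)} token blocks vs {len(dep_blocks)} parse blocks"
        )
    pos_cursor = 0
    doc.sentences = []
    for s_idx, block in enumerate(tok_blocks):
        tokens: list[Token] = []
        for line in block:
            parts = line.split("\t")
            if len(parts) != 3:
                raise StandoffParseError(
                    f"{doc.id}.tok: expected surface<TAB>baseform<TAB>POS, got {line!r}"
                )
            surface, base, pos = parts
            start = doc.text.find(surface, pos_cursor)
            if start < 0:
                raise StandoffParseError(
                    f"{doc.id}.tok: token {surface!r} not found in text after offset {pos_cursor}"
                )
            tokens.append(
                Token(len(tokens), surface, base, pos, start, start + len(surface))
            )
            pos_cursor = start + len(surface)
        dg = read_dependency_parse("\n".join(dep_blocks[s_idx]), tokens)
        in_sent = [
            p
            for p in doc.proteins.values()
            if tokens and tokens[0].char_start <= p.char_start and p.char_end <= tokens[-1].char_end
        ]
        tokens, dg = merge_protein_tokens(tokens, dg, in_sent)
        doc.sentences.append(Sentence(tokens, dg, index=s_idx))


def read_corpus(directory: str | Path) -> list[Document]:
    """Read every ``<id>.txt`` (+ ``.a1``/``.a2``/``.tok``/``.dep``) document."""
    directory = Path(directory)
    docs = []
    for txt_path in sorted(directory.glob("*.txt")):
        stem = txt_path.stem

        def _read(suffix: str) -> str:
            p = directory / f"{stem}{suffix}"
            return p.read_text() if p.exists() else ""

        doc = read_standoff_document(stem, txt_path.read_text(), _read(".a1"), _read(".a2"))
        attach_sentences(doc, _read(".tok"), _read(".dep"))
        docs.append(doc)
    return docs


def write_corpus(docs: Iterable[Document], directory: str | Path) -> None:
    """Write documents as ``.txt``/``.a1``/``.a2``/``.tok``/``.dep`` files."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for doc in docs:
        (directory / f"{doc.id}.txt").write_text(doc.text)
        a1 = "".join(
            f"{p.id}\tProtein {p.char_start} {p.char_end}\t{p.text}\n"
            for p in sorted(doc.proteins.values(), key=lambda p: int(p.id[1:]))
        )
        (directory / f"{doc.id}.a1").write_text(a1)
        (directory / f"{doc.id}.a2").write_text(write_a2(doc))
        tok_lines, dep_lines = [], []
        for sent in doc.sentences:
            for t in sent.tokens:
                # merged protein tokens are re-expanded lexically as their text
                tok_lines.append(f"{t.surface}\t{t.baseform}\t{t.pos}")
            tok_lines.append("")
            dep_lines.append(write_dependency_parse(sent).rstrip("\n"))
            dep_lines.append("")
        (directory / f"{doc.id}.tok").write_text("\n".join(tok_lines) + "\n")
        (directory / f"{doc.id}.dep").write_text("\n".join(dep_lines) + "\n")
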