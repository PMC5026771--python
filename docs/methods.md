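# Methods

This note records the modelling assumptions, parameter choices, and
numerical conventions behind `iem`, and what the synthetic experiments
do and do not demonstrate.

## Task and representation

The unit of analysis is a sentence with gold protein mentions, lexical
analyses (baseform, POS) and a basic Stanford dependency parse, all
taken as input — no parser is run.  Multi-word protein mentions are
merged into single tokens and their dependency edges redirected, so a
protein is always one node.

Events are represented per sentence as a labeled directed graph over
words.  Anchor words stand in for (possibly multi-word) triggers; a
node may carry several event-type labels (e.g. 'expression' anchoring
both Transcription and Gene Expression), and an ordered word pair
carries at most one role.  Converting annotations to graphs uses the
Head-Word rule: the anchor of a multi-word trigger is its in-span token
whose governor lies outside the span, ties to the rightmost token.
Exact trigger-span recovery is a non-goal: events decoded from graphs
carry the anchor word as their trigger span.

Two graph pathologies are handled explicitly.  A Positive Regulation
event taking a Gene Expression event anchored at the *same* word forms
a self-loop; such pairs are replaced by a single merged-label node
(`Gene_expression^Positive_regulation`) that expands back into the GE +
PR pair, with CAUSE edges attached to the PR component (regulation
carries cause semantics).  All other loops are dropped and sentences
whose role edges form a cycle are discarded outright, since cyclic
event-taking structures would license unboundedly many events.

Conversion back from graphs emits, per label: one event per protein
THEME edge (plain types); one event holding all protein THEME edges
(Binding — the simplest grouping consistent with "one or more protein
THEMEs"); and for event-taking types the cross-product of THEME options
(protein targets plus every event at event-node targets) with CAUSE
options.  When a node has CAUSE edges they bind every emitted event; a
CAUSE-less variant is *not* additionally emitted, because the graph
cannot distinguish it and emitting both would break the round-trip
identity events→graph→events on loop-free, acyclic, single-word-trigger
sentences — the invariant the reconstruction experiment measures.

## Trigger lexicons

Constituent words of gold triggers populate one lexicon per event type;
hyphenated words contribute their components and the original.  Entry
reliability is R_{w,e} = C_{w,e}/C_w, where C_w counts all token
occurrences of w in the training corpus (occurrences, not document
frequencies — the score is precision-like).  Entries and lookups are
lowercased.  Entries with R < 1 % are pruned.  A stemmed twin of every
lexicon is built with the Porter (1980) algorithm, implemented in the
package, and lookups max-pool over both lexicons and all derivations of
a token (surface, baseform, hyphen components, stems).

The lexicons gate the search space: words with no entry are fixed
negative, and candidate edges must start at a lexicon candidate and end
at a protein or another candidate.  When both Gene Expression and
Positive Regulation match a word, the merged composite label joins its
candidates so that merged gold events stay representable in learning.

## Features

Node vectors Φ(xᵢ) hold indicator features for surface/baseform/POS,
real-valued reliability features per matching event type, center-marked
n-grams (n = 2–4) of baseform:POS units with proteins rendered as
`PROTEIN` and boundary symbols at sentence edges, `Protein-Distance:d`
indicators per protein, and `Trigger-Distance:d` features valued at the
other word's maximal reliability (maximum when several candidates share
a distance).  Linear distances count word tokens only; punctuation
occupies no position — the convention that makes the package's three
documented distance examples (5, 2, and 4) mutually consistent, though
no published tokenizer specification exists for them.

Governor/modifier features are emitted in both a baseform-keyed and a
surface-keyed rendering of the focus word (`number:NNS-MOD(amod)-…` and
`numbers:NNS-GOV(dobj)-…` coexist); the documented examples use both
conventions and the duplication is harmless for a linear model.

Edge vectors add namespaced endpoint features, a path-length indicator,
and n-grams over three renderings of the shortest undirected dependency
path (ties broken to the lexicographically smallest token-index
sequence): the token sequence, the dependency sequence of
direction(relation) steps, and the interleaved token-dependency
sequence, whose n counts tokens with connecting steps riding along.
Direction tags follow the traversal: a hop from dependent to governor
renders `GOV(rel)`, the reverse `MOD(rel)`.

## Scoring and decoding

Node scores are ±w_e·Φ(xᵢ) (sign flipped for negative); each edge label
has its own weight vector, including 'negative'.  Validity requires
anchors to emit ≥ 1 THEME edge and role edges to leave anchors; invalid
assignments score −∞.  Because both conditions constrain a word only
jointly with its own out-edges, the exact optimum decomposes per source
word into a non-anchor option versus a best anchor option (per-type
argmax with one forced positive; per-edge argmax with one forced THEME,
chosen to minimise regret, ties to the smallest target index).  Ties
between positive and negative resolve to negative, making zero-weight
decoding deterministic and biasing toward precision.  A refinement pass
then relabels role edges ending at non-anchor non-protein words as
negative and demotes anchors that lose their last THEME edge, iterated
to a fixpoint (≤ n iterations); if the surviving role edges contain a
cycle the sentence yields no events.  Decoder optimality is guarded by
an exhaustive-enumeration oracle in the test suite rather than assumed.

## Learning

**Baseline (cost-sensitive PA).**  Mistakes cost one per false positive
and 3.8 per false negative label (a THEME/CAUSE substitution counts as
one of each).  The update is the closed-form Passive-Aggressive step
w ← w + τΔ with Δ = Ψ(gold) − Ψ(pred) and τ = loss/‖Δ‖², which makes
gold outscore the prediction by at least the cost under the pre-update
feature maps.  Training takes 20 passes in fixed document order (no
shuffling; the seed only controls synthetic data), storing after each
pass the running average of all interim weight vectors, computed with
the lazy-sum trick Σ_k w_k = (N+1)w_N − Σ n·δ_n so that averaging stays
sparse.

**Informed EM.**  The adjusted set D′ starts as the gold graphs.  The
first five rounds are M-steps only (initialisation; EM from a random
model would converge poorly).  Later rounds run an E step with the
previous round's averaged model: a prediction replaces a sentence's
adjusted graph only if it differs and passes every active constraint —

* *basic*: identical event-type set and typed argument triples
  (parent type, role, protein id or child event type) as the gold
  graph; triggers are ignored;
* *confidence*: (score(candidate) − score(current))/max(|current|,1e−8)
  ≥ α.  The ε floor keeps the ratio defined near zero scores;
* *non-overlapping* (optional): for each type, distinct candidate
  anchors ≥ distinct gold trigger *spans* (two events sharing one gold
  trigger need only one anchor);
* *distance*: every current anchor of type e has a same-type candidate
  anchor within β word tokens.  Only this direction is enforced — the
  documented two-triggers-four-apart example supports it; the converse
  is unstated.

M steps then multiply the cost by 10 for sentences whose graphs were
ever updated (the flag persists across rounds, the stronger and simpler
reading of "sentences with updated graphs").  With α above any
achievable ratio no update fires and the algorithm reproduces the
baseline bit for bit — a property the tests assert.  Default constants:
α = 0.3, β = 2 (the best-performing constrained configuration; a
conflicting printed value of β = 0.2 is treated as a typo for 2, the
value the parameter tables actually use), NOC off, 20 rounds, stopping
by held-out F.

## Evaluation

Greedy one-to-one event matching in deterministic order (gold sorted by
trigger offset then type), in three modes: exact (type, span, full
recursive arguments), approximate-span (predicted span inside the gold
span extended one word each side), approximate-recursive (nested
arguments on type + THEME only).  R = matched/gold, P = matched/pred
with 0/0 → 1, F1 harmonic with 0 when R+P = 0.  The reconstruction
experiment converts gold annotations to graphs and back and scores them
exactly; merged events recover the GE/PR loops, and the direction
(F with merging ≥ without) is asserted on loop fixtures, not a
magnitude, which is corpus-dependent.  The paired one-tailed t-test for
H₁: mean(a−b) > 0 uses the t distribution via scipy; all-zero
differences give p = 0.5 (t = 0), zero variance with nonzero mean gives
0 or 1.

## Synthetic corpora

The generator builds documents from sentence templates with
deterministic template-derived dependency trees, so the whole pipeline
is testable without any parser or external corpus.  It reproduces the
structural phenomena the method targets: single- and multi-word
proteins ("NF kappaB"), overlapping trigger vocabularies ('expression'
for Transcription and Gene Expression), nested regulations with
verb-determined CAUSE arguments, Binding with two THEMEs, GE/PR
trigger-sharing loops ('overexpressed'), and the head-word/modifier
span ambiguity ("increased levels" vs "increased").  Event-type
frequencies default to a GENIA-like mix (GE 0.24, PR 0.20, NR 0.12,
Binding 0.12, …).  `inject_span_inconsistency` re-annotates a seeded
fraction of multi-word triggers under the modifier convention, leaving
text unchanged; the defaults (30 % inconsistency, 300 training
sentences, held-out sets of 60 sentences) are the conditions of the
recovery experiment.

Because predictions carry anchor-word spans, held-out gold for exact
matching is first canonicalised through the same graph round-trip
(`canonicalize_corpus`), i.e. models are scored on the structure they
can in principle express.  What passing these tests shows is that the
machinery is correct and that annotation adjustment does not hurt — and
can help — under controlled span noise; it does **not** show
performance on real biomedical text, whose lexical variety, parse
errors and cross-sentence events the templates deliberately omit.
Experiment sizes (hundreds of sentences, 10–20 passes) were chosen as
the smallest at which the learning curves flatten.

## Known limitations

* The E step is hard (Viterbi) EM; a marginal (Inside–Outside-style)
  E step is out of scope.
* Constraints are hard gates; no softening or annealing schedule.
* Cross-sentence event arguments are dropped with a warning.
* Only GE^PR composites expand as merged events; other composite labels
  decode component-wise.
* Task-1 scope: modification (M) lines in `.a2` are ignored.
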