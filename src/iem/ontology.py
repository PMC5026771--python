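"""The GENIA event-type vocabulary and its argument-structure groups.

Nine event types, two role types (THEME, CAUSE).  The types fall into
three groups by the arguments they take:

* plain protein-taking events — exactly one protein THEME;
* multiple protein-taking events (Binding) — one or more protein THEMEs;
* event-taking events (the regulations) — one THEME (protein or event)
  and optionally one CAUSE (protein or event).
"""

from __future__ import annotations

GENE_EXPRESSION = "Gene_expression"
TRANSCRIPTION = "Transcription"
PROTEIN_CATABOLISM = "Protein_catabolism"
PHOSPHORYLATION = "Phosphorylation"
LOCALIZATION = "Localization"
BINDING = "Binding"
REGULATION = "Regulation"
POSITIVE_REGULATION = "Positive_regulation"
NEGATIVE_REGULATION = "Negative_regulation"

PLAIN_TYPES = frozenset(
    {GENE_EXPRESSION, TRANSCRIPTION, PROTEIN_CATABOLISM, PHOSPHORYLATION, LOCALIZATION}
)
MULTI_PROTEIN_TYPES = frozenset({BINDING})
EVENT_TAKING_TYPES = frozenset({REGULATION, POSITIVE_REGULATION, NEGATIVE_REGULATION})

EVENT_TYPES = PLAIN_TYPES | MULTI_PROTEIN_TYPES | EVENT_TAKING_TYPES

THEME = "THEME"
CAUSE = "CAUSE"
ROLES = (THEME, CAUSE)

#: Separator used to form composite (merged) node labels, e.g. the label
#: standing for a Gene Expression event nested under a Positive Regulation
#: event that shares its trigger word.
COMPOSITE_SEP = "^"

#: The one composite label that expands into a merged event pair.
MERGED_GE_PR = GENE_EXPRESSION + COMPOSITE_SEP + POSITIVE_REGULATION


def make_composite(*types: str) -> str:
    """Form a composite label from component event types (order-normalised)."""
    return COMPOSITE_SEP.join(sorted(types))


def composite_components(label: str) -> tuple[str, ...]:
    """Component event types of a (possibly composite) node label."""
    return tuple(label.split(COMPOSITE_SEP))


def is_composite(label: str) -> bool:
    return COMPOSITE_SEP in label
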