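"""Bio-entity annotation schema.

The corpus dialect understood by this package carries inline annotations
produced by a biomedical named-entity annotator.  Each annotation type has a
fixed span kind: an *entity* span covers a word or short word group (an enzyme
name, a fungal species, a gene ...), while a *sentence* span covers a whole
sentence describing an experimental property (kinetics, pH behaviour,
substrate specificity ...).
"""

from __future__ import annotations

ENTITY_SPAN = "entity"
SENTENCE_SPAN = "sentence"

#: Annotation type -> span kind for the 22 supported bio-entity types.
ENTITY_SCHEMA: dict[str, str] = {
    "AccessionNumber": ENTITY_SPAN,
    "ActivityAssayConditions": SENTENCE_SPAN,
    "Assay": ENTITY_SPAN,
    "Buffer": ENTITY_SPAN,
    "Characterization": ENTITY_SPAN,
    "Enzyme": ENTITY_SPAN,
    "Expression": SENTENCE_SPAN,
    "Family": ENTITY_SPAN,
    "Fungus": ENTITY_SPAN,
    "Gene": ENTITY_SPAN,
    "GlycosideHydrolase": ENTITY_SPAN,
    "Glycosylation": SENTENCE_SPAN,
    "Kinetics": SENTENCE_SPAN,
    "Laccase": ENTITY_SPAN,
    "Lipase": ENTITY_SPAN,
    "Peroxidase": ENTITY_SPAN,
    "pH": SENTENCE_SPAN,
    "ProductAnalysis": SENTENCE_SPAN,
    "Temperature": SENTENCE_SPAN,
    "SpecificActivity": SENTENCE_SPAN,
    "Substrate": ENTITY_SPAN,
    "SubstrateSpecificity": SENTENCE_SPAN,
}

ENTITY_SPAN_TYPES: tuple[str, ...] = tuple(
    t for t, k in ENTITY_SCHEMA.items() if k == ENTITY_SPAN
)
SENTENCE_SPAN_TYPES: tuple[str, ...] = tuple(
    t for t, k in ENTITY_SCHEMA.items() if k == SENTENCE_SPAN
)

#: Structural (non-annotation) tags of the document dialect.
STRUCTURAL_TAGS = ("Document", "ArticleTitle", "AbstractText", "RegistryNumber")

POSITIVE = "positive"
NEGATIVE = "negative"
CLASSES = (NEGATIVE, POSITIVE)
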