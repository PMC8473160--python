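"""Closed species vocabulary for roadside IAPS monitoring.

The surveyed invasive alien plant species (IAPS) are seven taxa recorded on
Danish state roads; *Heracleum* is typically dropped during cleaning because
too few images of it exist.  Two derived labels complete the vocabulary:
``NO_SPECIES`` for images without any annotation and ``MULTIPLE_SPECIES`` for
images whose annotations span more than one taxon.  ``MULTIPLE_SPECIES`` is
never annotated directly — it is inferred per image.
"""

from __future__ import annotations

from .errors import VocabularyError

# The seven recorded IAPS, alphabetical. Aggregate taxa (Heracleum,
# Reynoutria, Solidago) group the sibling species recorded under one name.
IAPS_SPECIES: tuple[str, ...] = (
    "Cytisus scoparius",
    "Heracleum",
    "Lupinus polyphyllus",
    "Pastinaca sativa",
    "Reynoutria",
    "Rosa rugosa",
    "Solidago",
)

#: The six species usually retained after cleaning (Heracleum removed).
RETAINED_SPECIES: tuple[str, ...] = tuple(
    s for s in IAPS_SPECIES if s != "Heracleum"
)

NO_SPECIES = "No species"
MULTIPLE_SPECIES = "Multiple species"

#: Full closed vocabulary of image-level class labels.
ALL_LABELS: tuple[str, ...] = IAPS_SPECIES + (NO_SPECIES, MULTIPLE_SPECIES)

#: Label order used by classification confusion matrices (six retained IAPS
#: plus the background class), matching the published tables.
CLASSIFICATION_LABELS: tuple[str, ...] = RETAINED_SPECIES + (NO_SPECIES,)


def is_iaps(label: str) -> bool:
    """True if *label* names an invasive species (not background/derived)."""
    return label in IAPS_SPECIES


def check_label(label: str) -> str:
    """Validate *label* against the closed vocabulary and return it."""
    if label not in ALL_LABELS:
        raise VocabularyError(f"unknown species label: {label!r}")
    return label
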