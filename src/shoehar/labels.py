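"""Activity label vocabularies and the mappings between them.

Three vocabularies are used along the pipeline:

* the raw 8-activity calibration protocol (two walking speeds),
* the 7-class classification vocabulary (walking speeds collapsed),
* the merged 5-class vocabulary (sitting/standing -> stationary,
  stair ascending/descending -> stair walking).

Class order in outputs is fixed to the conventional figure order so
confusion charts from different runs line up.
"""

from __future__ import annotations

from typing import Iterable, Sequence

SITTING = "sitting"
STANDING = "standing"
WALKING_SLOW = "walking_slow"
WALKING_BRISK = "walking_brisk"
WALKING = "walking"
STAIR_ASCENDING = "stair_ascending"
STAIR_DESCENDING = "stair_descending"
WEIGHT_CARRYING = "weight_carrying"
KNEELING = "kneeling"
STATIONARY = "stationary"
STAIR_WALKING = "stair_walking"
UNANNOTATED = "unannotated"

#: Raw calibration-protocol vocabulary, in protocol order.
RAW_ACTIVITIES: tuple[str, ...] = (
    SITTING,
    STANDING,
    WALKING_SLOW,
    WALKING_BRISK,
    STAIR_ASCENDING,
    STAIR_DESCENDING,
    WEIGHT_CARRYING,
    KNEELING,
)

#: 7-class classification vocabulary, in figure order.
SEVEN_CLASSES: tuple[str, ...] = (
    SITTING,
    STANDING,
    WALKING,
    STAIR_ASCENDING,
    STAIR_DESCENDING,
    WEIGHT_CARRYING,
    KNEELING,
)

#: Merged 5-class vocabulary.
FIVE_CLASSES: tuple[str, ...] = (
    STATIONARY,
    WALKING,
    STAIR_WALKING,
    WEIGHT_CARRYING,
    KNEELING,
)

#: Labels accepted in annotation logs (protocol or observer sources).
ANNOTATION_VOCABULARY: frozenset[str] = frozenset(RAW_ACTIVITIES) | frozenset(
    SEVEN_CLASSES
)

RAW_TO_SEVEN: dict[str, str] = {
    SITTING: SITTING,
    STANDING: STANDING,
    WALKING_SLOW: WALKING,
    WALKING_BRISK: WALKING,
    STAIR_ASCENDING: STAIR_ASCENDING,
    STAIR_DESCENDING: STAIR_DESCENDING,
    WEIGHT_CARRYING: WEIGHT_CARRYING,
    KNEELING: KNEELING,
}

SEVEN_TO_FIVE: dict[str, str] = {
    SITTING: STATIONARY,
    STANDING: STATIONARY,
    WALKING: WALKING,
    STAIR_ASCENDING: STAIR_WALKING,
    STAIR_DESCENDING: STAIR_WALKING,
    WEIGHT_CARRYING: WEIGHT_CARRYING,
    KNEELING: KNEELING,
}


def to_seven(label: str) -> str:
    """Map a raw protocol label (or an already 7-class label) to the 7-class vocabulary."""
    if label in RAW_TO_SEVEN:
        return RAW_TO_SEVEN[label]
    if label in SEVEN_CLASSES:
        return label
    raise ValueError(
        f"unknown activity label {label!r}; expected one of {sorted(ANNOTATION_VOCABULARY)}"
    )


def to_five(label: str) -> str:
    """Map a 7-class label to the merged 5-class vocabulary."""
    try:
        return SEVEN_TO_FIVE[label]
    except KeyError:
        raise ValueError(
            f"label {label!r} is not in the 7-class vocabulary {SEVEN_CLASSES}"
        ) from None


def map_labels(labels: Iterable[str], mapping: dict[str, str]) -> list[str]:
    """Apply a total label mapping to a sequence, erroring on out-of-domain labels."""
    out = []
    for lab in labels:
        try:
            out.append(mapping[lab])
        except KeyError:
            raise ValueError(f"label {lab!r} outside mapping domain") from None
    return out


def validate_labels(labels: Sequence[str], vocabulary: Iterable[str]) -> None:
    vocab = set(vocabulary)
    bad = sorted({lab for lab in labels if lab not in vocab})
    if bad:
        raise ValueError(f"unknown labels {bad}; allowed: {sorted(vocab)}")
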