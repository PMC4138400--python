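"""Oswestry Disability Index (ODI) scoring and the functional dichotomy.

The ODI is a 10-item self-report questionnaire on activities of daily living;
each item is answered on a 0–5 scale of increasing impairment.  Here the
answered items are averaged onto a 0–1 index (sum / (5 × n answered)), so a
fully disabled response scores 1.0.  Patients with a 3-month post-operative
index ≤ 0.6 are classed *functional*, the rest *nonfunctional*.

Missing items are excluded from numerator and denominator alike (the standard
ODI renormalisation convention); with all ten items answered the index
reduces to the usual sum/50.
"""
from __future__ import annotations

from dataclasses import dataclass
from enum import Enum
from typing import Optional, Sequence

from .exceptions import InvalidDataError, InvalidParameterError

__all__ = [
    "ODIResponse",
    "ODIIndex",
    "FunctionalStatus",
    "FUNCTIONAL_THRESHOLD",
    "odi_index",
    "classify_functional",
]

N_ITEMS = 10
ITEM_MAX = 5
#: Post-operative index at or below which a patient is "functional".
FUNCTIONAL_THRESHOLD = 0.6


class FunctionalStatus(str, Enum):
    FUNCTIONAL = "functional"
    NONFUNCTIONAL = "nonfunctional"


@dataclass(frozen=True)
class ODIResponse:
    """Raw questionnaire answers: 10 items in 0..5, ``None`` for unanswered."""

    item_scores: tuple[Optional[int], ...]
    subject_id: str = ""
    visit_id: str = ""

    def __post_init__(self) -> None:
        items = tuple(self.item_scores)
        if len(items) > N_ITEMS:
            raise InvalidDataError(f"at most {N_ITEMS} items, got {len(items)}")
        answered = [s for s in items if s is not None]
        if not answered:
            raise InvalidParameterError("at least one item must be answered")
        for s in answered:
            if not (isinstance(s, (int,)) and 0 <= s <= ITEM_MAX):
                raise InvalidDataError(f"item score {s!r} outside 0..{ITEM_MAX}")
        object.__setattr__(self, "item_scores", items)

    @property
    def n_answered(self) -> int:
        return sum(1 for s in self.item_scores if s is not None)


@dataclass(frozen=True)
class ODIIndex:
    """The 0–1 disability index and how many items produced it."""

    value: float
    n_answered: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.value <= 1.0):
            raise InvalidDataError(f"ODI index must lie in [0, 1], got {self.value}")


def odi_index(response: ODIResponse) -> ODIIndex:
    """Average the answered items onto the 0–1 scale.

    value = Σ answered scores / (5 × n answered).
    """
    answered = [s for s in response.item_scores if s is not None]
    value = sum(answered) / (ITEM_MAX * len(answered))
    return ODIIndex(value=value, n_answered=len(answered))


def classify_functional(odi_post: ODIIndex | float) -> FunctionalStatus:
    """Dichotomise a post-operative index at the 0.6 threshold (inclusive).

    index ≤ 0.6 → functional; index > 0.6 → nonfunctional.
    """
    value = odi_post.value if isinstance(odi_post, ODIIndex) else float(odi_post)
    if not (0.0 <= value <= 1.0):
        raise InvalidDataError(f"ODI index must lie in [0, 1], got {value}")
    if value <= FUNCTIONAL_THRESHOLD:
        return FunctionalStatus.FUNCTIONAL
    return FunctionalStatus.NONFUNCTIONAL


def odi_from_items(
    items: Sequence[Optional[int]], subject_id: str = "", visit_id: str = ""
) -> ODIIndex:
    """Convenience: score a raw item sequence in one call."""
    return odi_index(ODIResponse(tuple(items), subject_id=subject_id, visit_id=visit_id))
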