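"""Scoring of the 14-item Apathy Scale questionnaire.

The Apathy Scale (Starkstein) is a short self-report instrument used in
physiotherapy and epidemiology to screen for apathy — diminished motivation
not attributable to reduced consciousness, cognitive impairment, or
emotional distress.  Each of the 14 items is answered on a four-point
ordinal scale (No / A little / Yes / Very = 0/1/2/3 points); the item
points are summed and a total of 16 or more is judged apathetic, the
validated cutoff for the Japanese version of the instrument.

All 14 items use the same uniform response→point mapping.  Some published
variants of the instrument reverse-score a subset of items; ``score_response``
exposes a ``reverse_items`` argument for that, but it defaults to the
uniform mapping.
"""

from __future__ import annotations

from collections.abc import Iterable, Sequence
from dataclasses import dataclass

__all__ = [
    "APATHY",
    "NON_APATHY",
    "LABELS",
    "N_ITEMS",
    "MAX_ITEM_POINTS",
    "MAX_SCORE",
    "APATHY_CUTOFF",
    "RESPONSE_POINTS",
    "QuestionnaireResponse",
    "score_response",
    "classify_score",
    "classify_response",
]

APATHY = "apathy"
NON_APATHY = "non-apathy"
LABELS = (APATHY, NON_APATHY)

N_ITEMS = 14
MAX_ITEM_POINTS = 3
MAX_SCORE = N_ITEMS * MAX_ITEM_POINTS  # 42
APATHY_CUTOFF = 16

#: Verbal response options and their point values.
RESPONSE_POINTS = {"No": 0, "A little": 1, "Yes": 2, "Very": 3}


def _validate_items(items: Sequence[int]) -> tuple[int, ...]:
    items = tuple(int(v) for v in items)
    if len(items) != N_ITEMS:
        raise ValueError(f"expected {N_ITEMS} questionnaire items, got {len(items)}")
    for idx, value in enumerate(items, start=1):
        if value not in (0, 1, 2, 3):
            raise ValueError(f"item q{idx} has value {value}, outside 0..{MAX_ITEM_POINTS}")
    return items


@dataclass(frozen=True)
class QuestionnaireResponse:
    """One participant's 14 ordinal answers, already mapped to points 0..3."""

    items: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "items", _validate_items(self.items))

    @classmethod
    def from_words(cls, words: Iterable[str]) -> "QuestionnaireResponse":
        """Build a response from verbal options (``"No"`` .. ``"Very"``)."""
        try:
            return cls(tuple(RESPONSE_POINTS[w] for w in words))
        except KeyError as err:
            raise ValueError(f"unknown response option {err.args[0]!r}") from None

    @property
    def score(self) -> int:
        return score_response(self)


def score_response(response: QuestionnaireResponse | Sequence[int]) -> int:
    """Sum the 14 item points; the total lies in [0, 42].

    Parameters
    ----------
    response
        A :class:`QuestionnaireResponse` or a plain sequence of 14 values
        in {0, 1, 2, 3}.
    """
    items = response.items if isinstance(response, QuestionnaireResponse) else _validate_items(response)
    return int(sum(items))


def classify_score(score: int) -> str:
    """Map a questionnaire total to a label: apathy iff score >= 16."""
    score = int(score)
    if not 0 <= score <= MAX_SCORE:
        raise ValueError(f"score {score} outside valid range 0..{MAX_SCORE}")
    return APATHY if score >= APATHY_CUTOFF else NON_APATHY


def classify_response(response: QuestionnaireResponse | Sequence[int]) -> str:
    """Score a response and apply the cutoff in one step."""
    return classify_score(score_response(response))
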