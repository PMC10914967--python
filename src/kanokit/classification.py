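"""Kano evaluation grid: pair classification and per-item tabulation.

Each (functional, dysfunctional) answer pair maps to one of the six Kano
categories through the classic 5x5 evaluation table:

    functional \\ dysfunctional | LIKE MUST_BE NEUTRAL LIVE_WITH DISLIKE
    LIKE                        |  Q     A       A        A         O
    MUST_BE                     |  R     I       I        I         M
    NEUTRAL                     |  R     I       I        I         M
    LIVE_WITH                   |  R     I       I        I         M
    DISLIKE                     |  R     R       R        R         Q

The item's traditional category is the modal (highest-frequency) category
of its classified pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

from .core import (
    DEFAULT_TIE_BREAK,
    AnswerPair,
    CATEGORIES,
    KanoCategory,
    LikertAnswer,
)

_A = KanoCategory.A
_O = KanoCategory.O
_M = KanoCategory.M
_I = KanoCategory.I
_R = KanoCategory.R
_Q = KanoCategory.Q

#: The evaluation grid, keyed (functional, dysfunctional).
EVALUATION_GRID: dict[tuple[LikertAnswer, LikertAnswer], KanoCategory] = {}
_ROWS: dict[LikertAnswer, tuple[KanoCategory, ...]] = {
    LikertAnswer.LIKE: (_Q, _A, _A, _A, _O),
    LikertAnswer.MUST_BE: (_R, _I, _I, _I, _M),
    LikertAnswer.NEUTRAL: (_R, _I, _I, _I, _M),
    LikertAnswer.LIVE_WITH: (_R, _I, _I, _I, _M),
    LikertAnswer.DISLIKE: (_R, _R, _R, _R, _Q),
}
for _f, _row in _ROWS.items():
    for _d, _cat in zip(LikertAnswer, _row):
        EVALUATION_GRID[(_f, _d)] = _cat


class EmptyItemError(ValueError):
    """Raised when an item has no classified responses (N = 0)."""


def classify_pair(
    functional: LikertAnswer, dysfunctional: LikertAnswer
) -> KanoCategory:
    """Classify one answer pair via the evaluation grid.

    Total over the 5x5 domain; never raises for valid answer levels.
    """
    return EVALUATION_GRID[(LikertAnswer(functional), LikertAnswer(dysfunctional))]


@dataclass(frozen=True)
class ItemFrequencyTable:
    """Per-item counts over the six Kano categories.

    The hub of every downstream formula; N is the item's effective
    respondent count and always equals the sum of the six counts.
    """

    item_id: str
    counts: Mapping[KanoCategory, int]
    label: str = ""

    def __post_init__(self) -> None:
        full = {c: int(self.counts.get(c, 0)) for c in CATEGORIES}
        for c, v in full.items():
            if v < 0:
                raise ValueError(f"negative count for {c.value} in item {self.item_id}")
        object.__setattr__(self, "counts", full)
        if self.n == 0:
            raise EmptyItemError(f"item {self.item_id} has zero responses")

    @property
    def n(self) -> int:
        return sum(self.counts.values())

    def __getitem__(self, category: KanoCategory | str) -> int:
        return self.counts[KanoCategory(category)]


@dataclass(frozen=True)
class TraditionalResult:
    """Modal Kano category of an item, with tie diagnostics."""

    item_id: str
    category: KanoCategory
    tied: bool
    tie_set: frozenset[KanoCategory]

    def __post_init__(self) -> None:
        assert self.category in self.tie_set
        assert self.tied == (len(self.tie_set) > 1)


def tabulate_item(
    responses: Iterable[AnswerPair], item_id: str | None = None
) -> ItemFrequencyTable:
    """Classify and count all answer pairs of a single item."""
    counts = {c: 0 for c in CATEGORIES}
    the_id = item_id
    for pair in responses:
        if the_id is None:
            the_id = pair.item_id
        elif pair.item_id != the_id:
            raise ValueError(
                f"mixed item ids in tabulate_item: {the_id!r} vs {pair.item_id!r}"
            )
        counts[classify_pair(pair.functional, pair.dysfunctional)] += 1
    if the_id is None or sum(counts.values()) == 0:
        raise EmptyItemError("cannot tabulate an item with no responses")
    return ItemFrequencyTable(item_id=the_id, counts=counts)


def traditional_category(
    freq: ItemFrequencyTable,
    tie_break_order: Sequence[KanoCategory] = DEFAULT_TIE_BREAK,
) -> TraditionalResult:
    """Assign the max-frequency category, breaking ties by precedence.

    Ties are always surfaced (tied=True with the full tie set) so reports
    can flag ambiguous assignments.
    """
    best = max(freq.counts.values())
    tie_set = frozenset(c for c in CATEGORIES if freq.counts[c] == best)
    order = [KanoCategory(c) for c in tie_break_order]
    winner = min(tie_set, key=order.index)
    return TraditionalResult(
        item_id=freq.item_id,
        category=winner,
        tied=len(tie_set) > 1,
        tie_set=tie_set,
    )


def tabulate_dataset(dataset) -> list[ItemFrequencyTable]:
    """Tabulate every declared item of a SurveyDataset, in item order.

    Items left with zero responses after exclusions raise EmptyItemError.
    """
    by_item: dict[str, list[AnswerPair]] = {item_id: [] for item_id in dataset.item_ids}
    for pair in dataset.responses:
        by_item[pair.item_id].append(pair)
    return [tabulate_item(pairs, item_id=item_id) for item_id, pairs in by_item.items()]
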