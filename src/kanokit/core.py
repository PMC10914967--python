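"""Core domain types shared across the pipeline.

The atomic unit of a Kano survey is the answer *pair*: each service item is
asked twice, once positively phrased ("if the service is provided ...",
the functional form) and once negatively phrased ("if it is not provided
...", the dysfunctional form), each on the same five-level scale.
"""

from __future__ import annotations

import enum
import math
from dataclasses import dataclass, field


class LikertAnswer(enum.IntEnum):
    """Five-level answer scale used for both question forms.

    Integer codes follow the conventional Kano questionnaire ordering:
    1 = "I like it that way" ... 5 = "I dislike it that way".
    """

    LIKE = 1
    MUST_BE = 2
    NEUTRAL = 3
    LIVE_WITH = 4
    DISLIKE = 5


#: Accepted textual spellings for each answer level (matched after lowering
#: and trimming).  Survey exports vary wildly; integer codes 1-5 are always
#: accepted as well.
ANSWER_ALIASES: dict[str, LikertAnswer] = {
    "like": LikertAnswer.LIKE,
    "i like it that way": LikertAnswer.LIKE,
    "must-be": LikertAnswer.MUST_BE,
    "must be": LikertAnswer.MUST_BE,
    "must_be": LikertAnswer.MUST_BE,
    "it must be that way": LikertAnswer.MUST_BE,
    "neutral": LikertAnswer.NEUTRAL,
    "i am neutral": LikertAnswer.NEUTRAL,
    "live-with": LikertAnswer.LIVE_WITH,
    "live with": LikertAnswer.LIVE_WITH,
    "live_with": LikertAnswer.LIVE_WITH,
    "i can live with it that way": LikertAnswer.LIVE_WITH,
    "dislike": LikertAnswer.DISLIKE,
    "i dislike it that way": LikertAnswer.DISLIKE,
}


def parse_answer(token: object) -> LikertAnswer:
    """Parse an integer code (1-5) or a label into a LikertAnswer.

    Raises ValueError for anything unrecognised; callers decide whether to
    exclude the cell or abort.
    """
    if isinstance(token, LikertAnswer):
        return token
    if isinstance(token, bool):
        raise ValueError(f"not a Likert answer: {token!r}")
    if isinstance(token, (int, float)):
        if isinstance(token, float):
            if math.isnan(token) or token != int(token):
                raise ValueError(f"not a Likert answer: {token!r}")
            token = int(token)
        try:
            return LikertAnswer(token)
        except ValueError:
            raise ValueError(f"Likert code out of range 1-5: {token!r}") from None
    if isinstance(token, str):
        text = token.strip()
        if not text:
            raise ValueError("empty answer cell")
        try:
            return LikertAnswer(int(text))
        except ValueError:
            pass
        key = text.lower()
        if key in ANSWER_ALIASES:
            return ANSWER_ALIASES[key]
        raise ValueError(f"unknown answer token: {token!r}")
    raise ValueError(f"not a Likert answer: {token!r}")


class KanoCategory(str, enum.Enum):
    """The six Kano quality categories.

    A = attractive, O = one-dimensional, M = must-be, I = indifferent,
    R = reverse, Q = questionable.  The set is closed: classification never
    emits anything else.
    """

    A = "A"
    O = "O"
    M = "M"
    I = "I"
    R = "R"
    Q = "Q"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


CATEGORIES: tuple[KanoCategory, ...] = tuple(KanoCategory)

#: Default argmax tie-break precedence: safety-first, so an ambiguous item is
#: treated as the more obligatory category.
DEFAULT_TIE_BREAK: tuple[KanoCategory, ...] = (
    KanoCategory.M,
    KanoCategory.O,
    KanoCategory.A,
    KanoCategory.I,
    KanoCategory.R,
    KanoCategory.Q,
)


@dataclass(frozen=True)
class AnswerPair:
    """One respondent's functional/dysfunctional answers for one item."""

    respondent_id: str
    item_id: str
    functional: LikertAnswer
    dysfunctional: LikertAnswer


@dataclass
class SurveyDataset:
    """Validated respondent-level survey.

    ``items`` preserves questionnaire order; ``responses`` holds at most one
    AnswerPair per (respondent, item) cell.
    """

    items: list[tuple[str, str]]  # (item_id, label)
    responses: list[AnswerPair]

    def __post_init__(self) -> None:
        declared = {item_id for item_id, _ in self.items}
        seen: set[tuple[str, str]] = set()
        for pair in self.responses:
            if pair.item_id not in declared:
                raise ValueError(f"response references undeclared item {pair.item_id!r}")
            key = (pair.respondent_id, pair.item_id)
            if key in seen:
                raise ValueError(f"duplicate answer pair for {key}")
            seen.add(key)

    @property
    def item_ids(self) -> list[str]:
        return [item_id for item_id, _ in self.items]

    @property
    def respondent_ids(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for pair in self.responses:
            if pair.respondent_id not in seen:
                seen.add(pair.respondent_id)
                out.append(pair.respondent_id)
        return out

    @property
    def n_respondents(self) -> int:
        return len(self.respondent_ids)

    def responses_for(self, item_id: str) -> list[AnswerPair]:
        return [p for p in self.responses if p.item_id == item_id]


@dataclass
class RunConfig:
    """Tunable analysis parameters.

    ts_threshold / cs_threshold drive the mixed-attribute refinement
    (an item is mixed when total strength >= ts_threshold AND category
    strength <= cs_threshold, both on unrounded proportions).  Rounding
    settings are presentation-only and never feed back into decisions.
    """

    ts_threshold: float = 0.60
    cs_threshold: float = 0.06
    decimals: int = 2
    centroid_decimals: int = 4
    tie_break_order: tuple[KanoCategory, ...] = DEFAULT_TIE_BREAK
    quadrant_convention: str = "paper"  # or "classic"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.ts_threshold <= 1.0:
            raise ValueError("ts_threshold must lie in [0, 1]")
        if not 0.0 <= self.cs_threshold <= 1.0:
            raise ValueError("cs_threshold must lie in [0, 1]")
        order = tuple(KanoCategory(c) for c in self.tie_break_order)
        if sorted(c.value for c in order) != sorted(c.value for c in CATEGORIES):
            raise ValueError("tie_break_order must be a permutation of {A,O,M,I,R,Q}")
        object.__setattr__(self, "tie_break_order", order)
        if self.quadrant_convention not in ("paper", "classic"):
            raise ValueError("quadrant_convention must be 'paper' or 'classic'")


def round_half_away(x: float, decimals: int) -> float:
    """Round half away from zero (0.005 -> 0.01, -0.005 -> -0.01).

    Python's built-in round() is banker's rounding; reported survey tables
    conventionally round halves away from zero, so that is the display
    convention here.  A tiny epsilon guards against representation error in
    ratios of small integers.
    """
    scale = 10 ** decimals
    scaled = x * scale
    return math.copysign(math.floor(abs(scaled) + 0.5 + 1e-12), scaled) / scale
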