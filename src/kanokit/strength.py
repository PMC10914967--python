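"""Total/Category Strength and the mixed-attribute refinement.

The modal (traditional) assignment ignores how close the runner-up
category is.  Two strengths quantify that:

* Total Strength   TS = (M + O + A) / N          - does the item matter at all?
* Category Strength CS = (max - second max) / N  - how confident is the modal label?

where N sums all six category counts.  When TS >= 60% and CS <= 6% the
item is re-labelled a *mixed* attribute H(primary + secondary), named by
its two highest-frequency categories in descending count order.  Both
threshold comparisons are inclusive and applied to unrounded proportions;
rounding is presentation-only.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

from .classification import ItemFrequencyTable, TraditionalResult
from .core import CATEGORIES, DEFAULT_TIE_BREAK, KanoCategory, RunConfig

_TS_CATS = (KanoCategory.M, KanoCategory.O, KanoCategory.A)


def total_strength(freq: ItemFrequencyTable) -> float:
    """(M + O + A) / N, unrounded."""
    return sum(freq.counts[c] for c in _TS_CATS) / freq.n


def category_strength(freq: ItemFrequencyTable) -> float:
    """(largest count - second-largest count) / N, unrounded.

    The two largest are taken over the multiset of the six counts, so two
    categories sharing the maximum give CS = 0.
    """
    top2 = sorted(freq.counts.values(), reverse=True)[:2]
    return (top2[0] - top2[1]) / freq.n


@dataclass(frozen=True)
class OptimizedCategory:
    """Either a single Kano category or a mixed H(primary + secondary)."""

    primary: KanoCategory
    secondary: KanoCategory | None = None

    @property
    def is_mixed(self) -> bool:
        return self.secondary is not None

    @property
    def label(self) -> str:
        if self.secondary is None:
            return self.primary.value
        return f"H ({self.primary.value} + {self.secondary.value})"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.label


@dataclass(frozen=True)
class ItemAttributeResult:
    """One row of the attribute table: traditional label, TS, CS, optimized."""

    item_id: str
    traditional: KanoCategory
    ts: float
    cs: float
    optimized: OptimizedCategory


def _top_two(
    freq: ItemFrequencyTable, tie_break_order: Sequence[KanoCategory]
) -> tuple[KanoCategory, KanoCategory]:
    order = [KanoCategory(c) for c in tie_break_order]
    ranked = sorted(
        CATEGORIES, key=lambda c: (-freq.counts[c], order.index(c))
    )
    return ranked[0], ranked[1]


def optimize_category(
    freq: ItemFrequencyTable,
    traditional: TraditionalResult,
    config: RunConfig | None = None,
) -> ItemAttributeResult:
    """Apply the TS/CS mixed-attribute rule to one item.

    The rule applies uniformly to every item regardless of its modal
    category.  When it fires, the mixed label's primary component is the
    frequency argmax (the traditional category) and the secondary is the
    runner-up, ties broken by the configured precedence.
    """
    config = config or RunConfig()
    ts = total_strength(freq)
    cs = category_strength(freq)
    if ts >= config.ts_threshold and cs <= config.cs_threshold:
        first, second = _top_two(freq, config.tie_break_order)
        optimized = OptimizedCategory(primary=first, secondary=second)
    else:
        optimized = OptimizedCategory(primary=traditional.category)
    return ItemAttributeResult(
        item_id=freq.item_id,
        traditional=traditional.category,
        ts=ts,
        cs=cs,
        optimized=optimized,
    )
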