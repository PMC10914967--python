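"""Better-worse (SI/DSI) coefficients and the centroid quadrant matrix.

For each item, over the A/O/M/I responses only (reverse and questionable
answers carry no directional information and are excluded from the
denominator):

    SI  =  (A + O) / (A + O + M + I)           in [0, 1]
    DSI = -(O + M) / (A + O + M + I)           in [-1, 0]

SI near 1 means providing the service raises satisfaction strongly; DSI
near -1 means withholding it raises dissatisfaction strongly.  Items are
scattered against the centroid of the mean unrounded SI and the mean
unrounded |DSI| and split into four improvement-priority quadrants.

Quadrant naming follows the source convention of this pipeline, in which
the high-SI/low-|DSI| corner is called "must-be" and the low-SI/high-|DSI|
corner "attractive"; the more widespread better-worse convention swaps
those two names.  ``convention="classic"`` applies the swap.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from typing import Iterable, Sequence

from .classification import ItemFrequencyTable
from .core import KanoCategory


class UndefinedInfluenceError(ValueError):
    """Raised when an item has no A/O/M/I responses (denominator zero)."""


class Quadrant(enum.Enum):
    ONE_DIMENSIONAL = "one-dimensional"
    ATTRACTIVE = "attractive"
    INDIFFERENT = "indifferent"
    MUST_BE = "must-be"


#: Improvement priority, most urgent first.
QUADRANT_PRIORITY: tuple[Quadrant, ...] = (
    Quadrant.MUST_BE,
    Quadrant.ONE_DIMENSIONAL,
    Quadrant.ATTRACTIVE,
    Quadrant.INDIFFERENT,
)


def _denominator(freq: ItemFrequencyTable) -> int:
    denom = sum(
        freq.counts[c]
        for c in (KanoCategory.A, KanoCategory.O, KanoCategory.M, KanoCategory.I)
    )
    if denom == 0:
        raise UndefinedInfluenceError(
            f"item {freq.item_id}: all responses are R/Q; SI/DSI undefined"
        )
    return denom


def satisfaction_influence(freq: ItemFrequencyTable) -> float:
    """SI = (A + O) / (A + O + M + I), unrounded."""
    return (freq.counts[KanoCategory.A] + freq.counts[KanoCategory.O]) / _denominator(freq)


def dissatisfaction_influence(freq: ItemFrequencyTable) -> float:
    """DSI = -(O + M) / (A + O + M + I), unrounded."""
    return -(freq.counts[KanoCategory.O] + freq.counts[KanoCategory.M]) / _denominator(freq)


@dataclass(frozen=True)
class Centroid:
    """Matrix anchor: mean unrounded SI and mean unrounded |DSI|."""

    si_mean: float
    dsi_abs_mean: float


@dataclass
class ItemInfluence:
    """SI/DSI coefficients of one item plus its matrix placement."""

    item_id: str
    si: float
    dsi: float
    quadrant: Quadrant | None = None
    priority_rank: int | None = None


def compute_influences(freqs: Iterable[ItemFrequencyTable]) -> list[ItemInfluence]:
    return [
        ItemInfluence(
            item_id=f.item_id,
            si=satisfaction_influence(f),
            dsi=dissatisfaction_influence(f),
        )
        for f in freqs
    ]


def compute_centroid(influences: Sequence[ItemInfluence]) -> Centroid:
    """Arithmetic means of the unrounded SI and |DSI| values.

    Using unrounded coefficients matters: means of 2-dp rounded values
    drift by several thousandths from the true centroid.
    """
    if not influences:
        raise ValueError("cannot compute a centroid from zero items")
    n = len(influences)
    return Centroid(
        si_mean=sum(inf.si for inf in influences) / n,
        dsi_abs_mean=sum(abs(inf.dsi) for inf in influences) / n,
    )


def assign_quadrant(
    si: float, dsi: float, centroid: Centroid, convention: str = "paper"
) -> Quadrant:
    """Place an (SI, DSI) point relative to the centroid.

    A coordinate exactly equal to the centroid's counts as "high" (the
    boundary item gets the more actionable quadrant).  Membership depends
    only on |DSI|, never on the plot's axis orientation.
    """
    s = si >= centroid.si_mean
    d = abs(dsi) >= centroid.dsi_abs_mean
    if s and d:
        return Quadrant.ONE_DIMENSIONAL
    if not s and not d:
        return Quadrant.INDIFFERENT
    if s:  # high SI, low |DSI|
        return Quadrant.MUST_BE if convention == "paper" else Quadrant.ATTRACTIVE
    return Quadrant.ATTRACTIVE if convention == "paper" else Quadrant.MUST_BE


def priority_rank(influences: Sequence[ItemInfluence]) -> list[ItemInfluence]:
    """Order items for improvement and stamp 1-based ranks.

    Quadrant priority must-be > one-dimensional > attractive > indifferent;
    within a quadrant, descending |DSI|, then descending SI, then item_id.
    """
    for inf in influences:
        if inf.quadrant is None:
            raise ValueError(f"item {inf.item_id} has no quadrant assigned")
    ranked = sorted(
        influences,
        key=lambda inf: (
            QUADRANT_PRIORITY.index(inf.quadrant),
            -abs(inf.dsi),
            -inf.si,
            inf.item_id,
        ),
    )
    for rank, inf in enumerate(ranked, start=1):
        inf.priority_rank = rank
    return ranked


def build_matrix(
    freqs: Sequence[ItemFrequencyTable], convention: str = "paper"
) -> tuple[list[ItemInfluence], Centroid, list[ItemInfluence]]:
    """Full matrix stage: influences, centroid, quadrants and ranking.

    Items with undefined SI/DSI (all responses R/Q) are excluded from the
    centroid and returned unquadranted at the end of the first list.

    Returns (all influences in item order, centroid, ranked items).
    """
    defined: list[ItemInfluence] = []
    undefined: list[ItemInfluence] = []
    for f in freqs:
        try:
            defined.append(
                ItemInfluence(
                    item_id=f.item_id,
                    si=satisfaction_influence(f),
                    dsi=dissatisfaction_influence(f),
                )
            )
        except UndefinedInfluenceError:
            undefined.append(ItemInfluence(item_id=f.item_id, si=float("nan"), dsi=float("nan")))
    centroid = compute_centroid(defined)
    for inf in defined:
        inf.quadrant = assign_quadrant(inf.si, inf.dsi, centroid, convention)
    ranked = priority_rank(defined)
    return defined + undefined, centroid, ranked


def plot_matrix(
    influences: Sequence[ItemInfluence],
    centroid: Centroid,
    ax=None,
    si_axis: str = "x",
):
    """Scatter the items with centroid crosshairs (|DSI| on the other axis).

    ``si_axis`` selects which axis carries SI; quadrant membership is
    orientation-independent.  Returns the matplotlib Axes.
    """
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    xs, ys, labels = [], [], []
    for inf in influences:
        if inf.quadrant is None:
            continue
        si, d = inf.si, abs(inf.dsi)
        x, y = (si, d) if si_axis == "x" else (d, si)
        xs.append(x)
        ys.append(y)
        labels.append(inf.item_id)
    cx, cy = (
        (centroid.si_mean, centroid.dsi_abs_mean)
        if si_axis == "x"
        else (centroid.dsi_abs_mean, centroid.si_mean)
    )
    ax.scatter(xs, ys)
    for x, y, lab in zip(xs, ys, labels):
        ax.annotate(str(lab), (x, y), textcoords="offset points", xytext=(4, 4))
    ax.axvline(cx, linestyle="--", linewidth=1)
    ax.axhline(cy, linestyle="--", linewidth=1)
    ax.set_xlabel("SI" if si_axis == "x" else "|DSI|")
    ax.set_ylabel("|DSI|" if si_axis == "x" else "SI")
    return ax
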