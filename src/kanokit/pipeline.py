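"""End-to-end orchestration: frequencies -> attributes -> influence matrix."""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .classification import (
    ItemFrequencyTable,
    tabulate_dataset,
    traditional_category,
)
from .core import RunConfig, SurveyDataset
from .influence import Centroid, ItemInfluence, build_matrix
from .strength import ItemAttributeResult, optimize_category


@dataclass
class PipelineResult:
    """Everything the analysis produces, in item order."""

    config: RunConfig
    frequencies: list[ItemFrequencyTable]
    attributes: list[ItemAttributeResult]
    influences: list[ItemInfluence]
    centroid: Centroid
    ranked: list[ItemInfluence]

    def attribute_for(self, item_id: str) -> ItemAttributeResult:
        return next(a for a in self.attributes if a.item_id == item_id)

    def influence_for(self, item_id: str) -> ItemInfluence:
        return next(i for i in self.influences if i.item_id == item_id)


def analyze_frequencies(
    freqs: Sequence[ItemFrequencyTable], config: RunConfig | None = None
) -> PipelineResult:
    """Run the attribute and matrix stages on pre-tabulated frequencies."""
    config = config or RunConfig()
    attributes = [
        optimize_category(f, traditional_category(f, config.tie_break_order), config)
        for f in freqs
    ]
    influences, centroid, ranked = build_matrix(
        freqs, convention=config.quadrant_convention
    )
    return PipelineResult(
        config=config,
        frequencies=list(freqs),
        attributes=attributes,
        influences=influences,
        centroid=centroid,
        ranked=ranked,
    )


def analyze_dataset(
    dataset: SurveyDataset, config: RunConfig | None = None
) -> PipelineResult:
    """Classify, tabulate and analyze a respondent-level survey."""
    return analyze_frequencies(tabulate_dataset(dataset), config)
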