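"""Synthetic Kano surveys with known latent structure.

Each item carries a latent Kano category; a respondent answers with the
category's canonical pair with probability 1 - eps and with a pair drawn
uniformly from all 25 (functional, dysfunctional) combinations with
probability eps.  This uniform-contamination model keeps the expected
frequency of any category analytically tractable, so recovery experiments
have closed-form targets.

Latent Q is disallowed: a questionable answer signals respondent
inconsistency, not a genuine demand type.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np

from .classification import (
    ItemFrequencyTable,
    classify_pair,
    tabulate_dataset,
    traditional_category,
)
from .core import AnswerPair, KanoCategory, LikertAnswer, RunConfig, SurveyDataset
from .pipeline import analyze_frequencies

#: One designated evaluation-grid cell per category, chosen so that
#: classify_pair(canonical_pair(c)) == c.  Categories with several grid
#: cells (A has 3, I has 9, R has 7) use a fixed representative to keep
#: fixtures reproducible.
CANONICAL_PAIRS: dict[KanoCategory, tuple[LikertAnswer, LikertAnswer]] = {
    KanoCategory.A: (LikertAnswer.LIKE, LikertAnswer.NEUTRAL),
    KanoCategory.O: (LikertAnswer.LIKE, LikertAnswer.DISLIKE),
    KanoCategory.M: (LikertAnswer.NEUTRAL, LikertAnswer.DISLIKE),
    KanoCategory.I: (LikertAnswer.NEUTRAL, LikertAnswer.NEUTRAL),
    KanoCategory.R: (LikertAnswer.DISLIKE, LikertAnswer.LIKE),
    KanoCategory.Q: (LikertAnswer.LIKE, LikertAnswer.LIKE),
}

ALL_PAIRS: tuple[tuple[LikertAnswer, LikertAnswer], ...] = tuple(
    itertools.product(LikertAnswer, LikertAnswer)
)

LATENT_CATEGORIES = frozenset(
    {KanoCategory.A, KanoCategory.O, KanoCategory.M, KanoCategory.I, KanoCategory.R}
)


def _normalize_latent(latent) -> tuple[KanoCategory, ...]:
    if isinstance(latent, (KanoCategory, str)):
        cats = (KanoCategory(latent),)
    else:
        cats = tuple(KanoCategory(c) for c in latent)
    if not 1 <= len(cats) <= 2:
        raise ValueError("a latent spec is one category or a two-category mixture")
    for cat in cats:
        if cat not in LATENT_CATEGORIES:
            raise ValueError(
                f"latent category must be one of A/O/M/I/R, got {cat.value}"
            )
    return cats


@dataclass(frozen=True)
class SyntheticSurveyConfig:
    """Design of a simulated survey.

    ``items`` maps item_id -> latent spec: either a single Kano category
    (Q disallowed) or a pair of categories, meaning an even two-category
    mixture (the kind of item the TS/CS refinement flags as mixed).
    ``noise_rate`` is the uniform-contamination probability eps.
    """

    n_respondents: int
    items: tuple[tuple[str, object], ...]
    noise_rate: float = 0.0
    seed: int = 0
    sample_within_category: bool = False  # draw uniformly among the category's grid cells

    def __post_init__(self) -> None:
        if self.n_respondents < 1:
            raise ValueError("n_respondents must be >= 1")
        if not self.items:
            raise ValueError("at least one item required")
        items = tuple((str(i), _normalize_latent(c)) for i, c in self.items)
        object.__setattr__(self, "items", items)
        if not 0.0 <= self.noise_rate <= 1.0:
            raise ValueError("noise_rate must lie in [0, 1]")


def _category_cells(cat: KanoCategory) -> list[tuple[LikertAnswer, LikertAnswer]]:
    return [p for p in ALL_PAIRS if classify_pair(*p) == cat]


def simulate_survey(config: SyntheticSurveyConfig) -> SurveyDataset:
    """Draw a respondent-level survey from the contamination model.

    Deterministic given the config (all randomness from one seeded
    generator); at eps = 0 every response is the canonical pair.
    """
    rng = np.random.default_rng(config.seed)
    width = len(str(config.n_respondents))
    responses: list[AnswerPair] = []
    for item_id, latent in config.items:
        if config.sample_within_category:
            cells = [p for cat in latent for p in _category_cells(cat)]
        else:
            cells = [CANONICAL_PAIRS[cat] for cat in latent]
        if len(cells) == 1:
            signal = cells * config.n_respondents
        else:
            idx = rng.integers(0, len(cells), size=config.n_respondents)
            signal = [cells[i] for i in idx]
        noisy = rng.random(config.n_respondents) < config.noise_rate
        noise_idx = rng.integers(0, len(ALL_PAIRS), size=config.n_respondents)
        for r in range(config.n_respondents):
            f, d = ALL_PAIRS[noise_idx[r]] if noisy[r] else signal[r]
            responses.append(
                AnswerPair(
                    respondent_id=f"r{r + 1:0{width}d}",
                    item_id=item_id,
                    functional=f,
                    dysfunctional=d,
                )
            )
    items = [(item_id, f"synthetic item {item_id}") for item_id, _ in config.items]
    return SurveyDataset(items=items, responses=responses)


def emit_fixture_from_frequencies(
    freqs: Sequence[ItemFrequencyTable],
) -> SurveyDataset:
    """Reconstruct a respondent-level dataset from per-item category counts.

    For each item, emits exactly counts[c] copies of category c's designated
    pair, assigned to respondents r1, r2, ... in a fixed category order, so
    tabulating the result reproduces the input frequencies exactly.
    Item totals may differ; respondent ids are reused across items.
    """
    if not freqs:
        raise ValueError("no frequency tables given")
    n_max = max(f.n for f in freqs)
    width = len(str(n_max))
    responses: list[AnswerPair] = []
    for f in freqs:
        r = 0
        for cat in KanoCategory:
            func, dys = CANONICAL_PAIRS[cat]
            for _ in range(f.counts[cat]):
                r += 1
                responses.append(
                    AnswerPair(
                        respondent_id=f"r{r:0{width}d}",
                        item_id=f.item_id,
                        functional=func,
                        dysfunctional=dys,
                    )
                )
    items = [(f.item_id, f.label or f.item_id) for f in freqs]
    return SurveyDataset(items=items, responses=responses)


@dataclass
class RecoveryReport:
    """Outcome of a category-recovery experiment."""

    replicates: int
    per_item_traditional_recovery: dict[str, float]
    per_item_optimized_recovery: dict[str, float]
    per_category_recovery: dict[KanoCategory, float]
    mean_abs_si_error: float
    mean_abs_dsi_error: float


def expected_influences(latent, eps: float) -> tuple[float, float]:
    """Analytic expected (SI, DSI) for a latent spec under eps-noise.

    Under uniform contamination the expected share of category c is
    (1-eps) * P(signal is c) + eps * |cells(c)| / 25; SI/DSI are the
    ratios of those expectations (exact as N -> infinity).  A two-category
    mixture splits the signal mass evenly.
    """
    cats = _normalize_latent(latent)
    counts = {c: eps * len(_category_cells(c)) / 25.0 for c in KanoCategory}
    for cat in cats:
        counts[cat] += (1.0 - eps) / len(cats)
    denom = sum(
        counts[c]
        for c in (KanoCategory.A, KanoCategory.O, KanoCategory.M, KanoCategory.I)
    )
    si = (counts[KanoCategory.A] + counts[KanoCategory.O]) / denom
    dsi = -(counts[KanoCategory.O] + counts[KanoCategory.M]) / denom
    return si, dsi


def recovery_experiment(
    config: SyntheticSurveyConfig,
    replicates: int,
    run_config: RunConfig | None = None,
) -> RecoveryReport:
    """Simulate -> full pipeline -> compare recovered categories to latents.

    Traditional recovery asks whether the modal category is one of the
    latent spec's components; optimized recovery asks the same of the
    optimized label's primary component.  SI/DSI errors are measured
    against the eps-mixture analytic expectation.  Per-category recovery
    aggregates single-latent items only (a mixture has no single truth).
    """
    if replicates < 1:
        raise ValueError("replicates must be >= 1")
    run_config = run_config or RunConfig()
    latents = dict(config.items)
    trad_hits = {i: 0 for i, _ in config.items}
    opt_hits = {i: 0 for i, _ in config.items}
    si_err = 0.0
    dsi_err = 0.0
    n_influence = 0
    base_rng = np.random.default_rng(config.seed)
    for rep in range(replicates):
        rep_seed = int(base_rng.integers(0, 2**31 - 1))
        rep_config = SyntheticSurveyConfig(
            n_respondents=config.n_respondents,
            items=config.items,
            noise_rate=config.noise_rate,
            seed=rep_seed,
            sample_within_category=config.sample_within_category,
        )
        dataset = simulate_survey(rep_config)
        freqs = tabulate_dataset(dataset)
        result = analyze_frequencies(freqs, run_config)
        for attr in result.attributes:
            latent = latents[attr.item_id]
            if attr.traditional in latent:
                trad_hits[attr.item_id] += 1
            if attr.optimized.primary in latent:
                opt_hits[attr.item_id] += 1
        for inf in result.influences:
            if inf.quadrant is None:
                continue
            exp_si, exp_dsi = expected_influences(latents[inf.item_id], config.noise_rate)
            si_err += abs(inf.si - exp_si)
            dsi_err += abs(inf.dsi - exp_dsi)
            n_influence += 1
    per_item_trad = {i: h / replicates for i, h in trad_hits.items()}
    per_item_opt = {i: h / replicates for i, h in opt_hits.items()}
    singles = [(i, c[0]) for i, c in config.items if len(c) == 1]
    per_category: dict[KanoCategory, float] = {}
    for cat in sorted({c for _, c in singles}, key=lambda c: c.value):
        ids = [i for i, c in singles if c == cat]
        per_category[cat] = sum(per_item_trad[i] for i in ids) / len(ids)
    return RecoveryReport(
        replicates=replicates,
        per_item_traditional_recovery=per_item_trad,
        per_item_optimized_recovery=per_item_opt,
        per_category_recovery=per_category,
        mean_abs_si_error=si_err / max(n_influence, 1),
        mean_abs_dsi_error=dsi_err / max(n_influence, 1),
    )
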