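# Methods

## Model and procedure

kanokit implements the two-dimensional Kano classification of service
demand. Each survey item is asked in a functional ("if provided") and a
dysfunctional ("if not provided") phrasing on the five-level scale
like / must-be / neutral / live-with / dislike (codes 1–5). The pair of
answers indexes the 5×5 evaluation grid, whose cells partition into six
categories: 3 attractive (A), 1 one-dimensional (O), 3 must-be (M),
9 indifferent (I), 7 reverse (R) and 2 questionable (Q). Per item, the
category counts over respondents form the frequency table that every
downstream statistic consumes; the *traditional* category is the count
argmax.

The refinement stage computes, on the full six-category total N:

- TS = (M + O + A) / N,
- CS = (largest count − second-largest count) / N,

and re-labels an item as the mixed attribute H(first + second) — its two
highest-frequency categories in descending count order — when TS ≥ 0.60
and CS ≤ 0.06. Both comparisons are inclusive and applied to **unrounded**
proportions: with N = 101 a CS of 5/101 ≈ 0.0495 must pass "≤ 6%" on its
exact value, and decisions must not depend on display precision. The rule is
applied uniformly to every item, whatever its modal category.

The matrix stage computes, excluding R and Q answers from the denominator,

- SI = (A + O) / (A + O + M + I) ∈ [0, 1],
- DSI = −(O + M) / (A + O + M + I) ∈ [−1, 0],

scatters items against the centroid (mean unrounded SI, mean unrounded
|DSI|), and assigns quadrants by comparing each item's unrounded SI and
|DSI| to the centroid. The centroid intentionally averages *unrounded*
coefficients: averaging the 2-dp table values shifts the SI coordinate by
about 0.002, enough to flip items that sit close to the boundary.
Improvement priority across quadrants is must-be > one-dimensional >
attractive > indifferent; within a quadrant items are ordered by
descending |DSI|, then descending SI, then item id (a documented,
deterministic tie-break).

## Conventions and degenerate inputs

- **Quadrant naming.** This pipeline's source convention names the
  high-SI/low-|DSI| corner "must-be" and low-SI/high-|DSI| "attractive";
  the more widespread better–worse convention swaps those two names. The
  default follows the source; `RunConfig(quadrant_convention="classic")`
  relabels. Membership itself is unambiguous either way, and depends only
  on |DSI|, never on which axis a plot puts SI on.
- **Boundary points** (a coordinate exactly equal to the centroid's) count
  as "high", so a boundary item lands in the more actionable quadrant.
  This case cannot arise in the bundled example.
- **Argmax ties.** Configurable precedence, default M > O > A > I > R > Q
  (safety-first: an ambiguous item is treated as more obligatory). Ties are
  always flagged (`tied=True`, full tie set) so reports surface them. The
  same precedence breaks the runner-up tie inside a mixed label.
- **Rounding** is presentation-only: half-away-from-zero at 2 decimals for
  table values and 4 for the centroid. No value in the bundled example is a
  half-tie, so the choice is about determinism, not outcomes.
- **R/Q handling.** Reverse and questionable answers count in the frequency
  table and in TS/CS denominators, and may even be the modal category; they
  are excluded only from the SI/DSI denominator. An item whose answers are
  *all* R/Q has undefined SI/DSI: it is excluded from the centroid and
  reported without a quadrant rather than silently dropped.
- **Missing or unparseable answers** are excluded cell-wise — that
  (respondent, item) pair only, never the whole respondent — and logged.
  Per-item N may therefore differ across items; every formula already
  operates on per-item totals. An item with zero valid responses, or an
  all-zero frequency row, is a hard error, not a sentinel.
- **Answer parsing** accepts integer codes 1–5 and case-insensitive labels
  (both short tokens and the full questionnaire phrasings). Unknown tokens
  are logged and excluded, never guessed.

## Psychometrics

Standardized Cronbach's alpha (k·r̄ / (1 + (k−1)·r̄) from the mean
off-diagonal Pearson correlation), the overall Kaiser–Meyer–Olkin measure
(squared correlations against squared anti-image partial correlations from
the inverse correlation matrix), and Bartlett's sphericity test
(χ² = −(n−1−(2k+5)/6)·ln|R|, df = k(k−1)/2) are computed separately for
the functional and dysfunctional instruments. Pearson correlations on the
integer Likert codes follow the convention of standard statistics packages;
polychoric alternatives are out of scope. Respondents with any missing cell
are dropped (complete-case) with the count reported. Zero-variance items are
excluded from alpha with a warning; perfectly collinear items make KMO and
Bartlett fail loudly. p-values display at 4 decimals with a "<0.0001" floor —
a printed "0.000" is truncation, never a computed zero. These statistics are
verified against independent oracles (a covariance-form alpha on z-scored
columns, regression-residual partial correlations, an eigenvalue
log-determinant) to 1e-8 on seeded matrices; reliability values reported for
any particular published survey are not reproducible without its raw
responses and are not targets.

The Kendall sample-size helper returns ceil(n_vars × multiplier ×
attrition_inflation) for the 5× and 10× multipliers (defaults 5/10, 1.2
inflation, e.g. 14 variables → 84–168). `response_rate` is the plain
valid/collected quotient.

## Synthetic data

`simulate_survey` gives every item a latent category (A/O/M/I/R; latent Q is
disallowed because a questionable answer is an inconsistency artifact, not a
demand type) or an even two-category mixture. A respondent emits the
latent's canonical grid cell with probability 1−ε and a pair drawn uniformly
from all 25 cells with probability ε. Uniform contamination is the simplest
exchangeable error model and keeps every derived statistic analytic: the
expected share of category c is (1−ε)·P(signal = c) + ε·|cells(c)|/25, so
recovery experiments have closed-form targets (`expected_influences`).
Canonical cells are fixed designated representatives (A→(like, neutral),
O→(like, dislike), M→(neutral, dislike), I→(neutral, neutral),
R→(dislike, like)) so fixtures are byte-reproducible;
`sample_within_category=True` instead draws uniformly among a category's
grid cells. All randomness comes from one seeded generator: equal configs
produce identical datasets.

The default recovery experiment mirrors the bundled study's design — 101
respondents, 14 items whose latent census matches the example's optimized
census (1 M, 4 O, 2 A, 2 I plus five two-category mixtures) — at ε = 0.05,
200 replicates. What the generator does **not** emulate: respondent-level
heterogeneity (everyone shares one error rate), correlated errors across
items, demographic covariates, and acquiescence or ordering effects. Passing
tests therefore show the pipeline's arithmetic and decision rules are
correct under a clean error model, not that any real survey's answers are
well calibrated.

## Known limitations

- Single evaluation grid only; analytical/fuzzy Kano variants are out of
  scope, as are significance tests for category assignments and
  importance-weighted satisfaction indices.
- SI/DSI treat the A/O/M/I mix as the full signal; items dominated by R
  answers get coefficients computed on a small denominator and should be
  read with their effective N.
- The quadrant split is a descriptive device anchored at the sample
  centroid; membership of near-centroid items is unstable under resampling,
  which the recovery experiment makes visible for mixture items.
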