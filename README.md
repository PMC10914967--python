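# kanokit

Kano-model analysis of paired functional/dysfunctional Likert surveys, built
for service-quality studies (the bundled example is a patient-demand survey of
general-practice teaching-clinic services).

A Kano questionnaire asks every item twice — "if this service is provided,
how do you feel?" (functional form) and "if it is not provided, how do you
feel?" (dysfunctional form) — each on a five-level scale from *I like it that
way* (1) to *I dislike it that way* (5). The answer pair places the item in
one of six quality categories:

| | dysfunctional: like | must-be | neutral | live-with | dislike |
|---|---|---|---|---|---|
| **functional: like** | Q | A | A | A | O |
| **must-be / neutral / live-with** | R | I | I | I | M |
| **dislike** | R | R | R | R | Q |

A = attractive, O = one-dimensional, M = must-be, I = indifferent,
R = reverse, Q = questionable.

The pipeline then computes, per item, from the category counts:

- **Total Strength** TS = (M + O + A) / N — does the item matter at all;
- **Category Strength** CS = (max − second max) / N — how confident the
  modal label is; items with TS ≥ 60% and CS ≤ 6% are re-labelled *mixed*
  H(first + second) by their two most frequent categories;
- **better–worse coefficients** SI = (A + O)/(A + O + M + I) and
  DSI = −(O + M)/(A + O + M + I), with R/Q answers excluded from the
  denominator;
- a **quadrant matrix** anchored at the centroid of the mean unrounded SI
  and mean unrounded |DSI|, with an improvement-priority ordering across
  quadrants (must-be > one-dimensional > attractive > indifferent).

Instrument-quality statistics (standardized Cronbach's alpha, KMO,
Bartlett's sphericity), the Kendall 5–10×-variables sample-size rule, and a
seeded synthetic-survey generator with known latent categories round out the
toolkit.

## Worked example

```python
from kanokit import analyze_frequencies, round_half_away
from kanokit.datasets import teaching_clinic_frequencies

result = analyze_frequencies(teaching_clinic_frequencies())
a = result.attribute_for("2")
print(a.traditional.value,
      round_half_away(a.cs, 2), round_half_away(a.ts, 2),
      a.optimized.label)
print(f"centroid ({result.centroid.si_mean:.4f}, {result.centroid.dsi_abs_mean:.4f})")
top = result.ranked[0]
print(top.item_id, top.quadrant.value, round_half_away(top.si, 2), round_half_away(top.dsi, 2))
```

prints

```
M 0.02 0.9 H (M + A)
centroid (0.5650, 0.5607)
3 must-be 0.58 -0.5
```

Item 2 ("various convenient ways of registration") is modally must-be, but
its runner-up (attractive, 32 vs 34 of 101 answers) is so close (CS = 0.02)
while almost every answer is directional (TS = 0.90) that it is re-labelled
the mixed attribute H (M + A). The matrix centroid sits at mean SI 0.5650
and mean |DSI| 0.5607, and the top improvement priority is item 3, in the
high-SI/low-|DSI| quadrant.

The same analysis runs from the shell:

```bash
kano run --input survey.csv --layout long --out report/      # respondent-level
kano run --input freqs.csv  --layout freq --out report/      # pre-tabulated counts
kano simulate --config design.json --out synthetic.csv
kano psychometrics --input wide.csv --out psych.json
```

`kano run` writes an attribute table (item, traditional, CS, TS, optimized),
an influence table (item, SI, DSI), a matrix JSON (centroid, per-item
quadrant and priority rank) and a run log with the configuration and any
excluded answer cells.

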