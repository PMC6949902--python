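# Methods

## Problem setting

Two self-report instruments measure the same construct — usual dietary
intake of food groups relevant to age-related macular degeneration — at
very different cost: a 145-item food-frequency questionnaire (FFQ,
12-month recall, categorical frequency options) and a 36-item short
dietary questionnaire (SDQ, last-week recall, numeric answers in mixed
units). Neither observes true intake; the analysis question is whether
the cheap instrument agrees with the expensive one well enough to screen
patients in clinic. The package therefore implements three layers:
harmonization of both instruments onto serves/day, a 30-point
diet-adequacy score, and method-comparison statistics on the paired
outputs.

## Harmonization model

**FFQ.** Each item response is a frequency label drawn from a fixed
ordered set; the label→fraction-of-a-day map (0, 0.02, 0.07, 0.14, 0.43,
0.79, 1, 2.5, 4) is part of the schema and validated to be non-decreasing
with a zero first entry. Daily grams for an item are
`frequency × portion_mass_g × seasonal_factor`. Group serves divide the
group's summed grams by a per-group standard serve mass (fruit 150 g,
vegetables 75 g, water 250 g, …) declared in the schema. Two groups use a
different currency because their items have incommensurate portions:
discretionary foods accumulate energy and divide by 600 kJ/serve;
alcoholic drinks accumulate ethanol grams and divide by the 10 g standard
serve. Seasonal factors default to 1.0 (no adjustment): per-item
multiplicative factors are supported as configuration, but no market data
are bundled, so the default is the identity.

**Free-text items.** Cereal and oil "please specify" questions resolve
the named product against a bundled ~20-entry composition table (exact
match after trimming, case-folding and whitespace collapsing). A matched
cereal's GI class decides whether its grams count toward the low- or
high-GI cereal group; unmatched names fall back to the item's schema
defaults and are logged, never dropped.

**SDQ.** Per-day answers pass through; per-week answers divide by 7;
times-per-week items use the instrument's stated one-time-equals-one-serve
assumption. Alcohol answers are drinks of a named type, converted to
standard serves via `drinks × ethanol_g_per_drink / 10` before the weekly
division. The bundled drink table (beer 13.6 g, wine 15.4 g, spirits
10 g per reported drink) is configurable.

**Missing answers.** Unanswered cells are missing at parse time, never
zero. Within a group, missing items contribute zero when under 20% of
the group's items are missing (a respondent skipping one fruit line
almost surely eats none of it); at or above 20% the group is marked
missing (NaN), scored 0 with a flag, and excluded pairwise from
correlations and proportion denominators. The threshold is an argument of
both pipelines.

**Disjoint vegetable groups.** "Total vegetables" and "dark green leafy
vegetables" are modelled as disjoint item sets: each item belongs to
exactly one group. This keeps profile additivity exact (a respondent's
profile is the group-wise sum of single-item contributions). Reported
totals for the vegetable rows are therefore conservative relative to a
convention that double-counts leafy vegetables in the total.

## Scoring

Criteria are per-group ordered bands [lower, upper) on serves/day with
integer points; bands must tile [0, ∞) exactly, and a value on a boundary
falls in the higher band (inclusive lower bounds). Adequacy groups
require non-decreasing points with intake, moderation groups
non-increasing; validation enforces both, plus the constraint that group
maxima sum to the 30-point total. The bundled default gives 15 groups 2
points each, with cut points anchored on Australian adult dietary
guidance (vegetables ≥5 serves/day → 2 points, ≥3 → 1; fruit ≥2/day → 2;
fish ≥2 serves/week → 2; discretionary <0.5 serve/day → 2; processed meat
scored 2 only below 0.02 serves/day — the smallest nonzero frequency the
FFQ can encode, i.e. "effectively never"; …). White meat is reported in
profiles but unscored. The exact band placement of any published
instrument varies; the table is data, not code, and every analysis
accepts a user criteria file. "Meeting the recommendation" for
cohort-level proportions means scoring the group's maximum points.

## Agreement statistics

Differences are oriented FFQ − SDQ (configurable). Bland–Altman uses the
sample SD (n−1) and limits of agreement at mean ± 2·SD — the multiplier
is exactly 2 by the convention adopted here, not 1.96, and is a
threshold parameter. Proportional bias is ordinary least squares of
difference on pair mean with classical normal-theory t inference
(two-sided p, 95% CI); zero variance of pair means yields a flagged
degenerate result rather than an error. Pearson r uses the standard
product-moment formula with p from t = r·√((n−2)/(1−r²)) on n−2 df;
constant inputs yield flagged NaN. Correlations are reported per food
group × age stratum (<80, ≥80, pooled) on pairwise-complete respondents;
strata with fewer than 3 complete pairs are emitted with undefined r.
|r| < 0.30 is flagged negligible. No multiple-testing adjustment is
applied across the group × stratum grid — the analysis reports raw
p-values. At least 3 pairs are required for any agreement statistic.

## Synthetic cohort generator

The generator emulates the study conditions, not any particular cohort's
data: n = 155 respondents; ages normal(78, 8), rounded to integer years
and truncated to [50, 100]; per-group latent usual intake log-normal with
medians set near published cohort-level FFQ daily means (fruit 1.8,
vegetables 3.15, water 5.6 serves/day, …; fats/oils, never tabulated,
1.5) and log-scale dispersion 0.5. Observations multiply the latent value
by mean-1 log-normal noise (FFQ CV 0.25; SDQ CV 0.35 — the short
instrument is noisier); the SDQ additionally shifts the latent value by a
per-group additive bias before noise, defaulting to −1 serve/day for
vegetables, water and discretionary foods to mirror the systematic
under-reporting seen on short screeners, truncated at zero. An optional
missing-completely-at-random rate blanks answer cells.

FFQ emission spreads each group's observed intake evenly over up to three
of the group's items and quantizes each item's implied daily frequency to
the nearest label (ties toward the lower option) — the inverse of the
label map. This bounds the zero-noise reconstruction error per carrier
item by half the largest gap between adjacent label values (0.75/day)
times the item-to-group serve-mass ratio, a bound the tests assert;
intakes implying more than 4/day on an item saturate at the top label.
SDQ emission reports each group on its first item in that item's declared
unit, rounded to 2 decimals. Generation is a pure function of
(config, seed) via a single `numpy` Generator stream.

For parameter-recovery checks of the agreement statistics the full
pipeline is the wrong instrument — discrete scores cannot realize an
exactly normal difference distribution — so
`paired_totals_with_difference` draws paired totals whose differences are
i.i.d. Normal(δ, σ²) by splitting a known difference across the two
instruments around a common pair mean. Tests recover δ within 4σ/√n and
the limits of agreement within 10% at n = 5000 for δ = −1.5, σ = 4.2 and
two other settings.

What passing tests do **not** show about real data: the generator has no
item-level correlation structure within groups, no day-of-week or
seasonal effects, no differential recall by age or disease stage, and its
noise is purely multiplicative log-normal — so between-instrument
correlations in synthetic cohorts are more homogeneous across food groups
than published ones (where r spans roughly 0.01–0.84), and real-data
agreement may be worse than synthetic agreement in ways the error model
cannot express.

## Numerical and design choices

- All serve arithmetic in double precision; no rounding before scoring;
  report rendering rounds serves to 2 decimals, r to 2, scores stay
  integers.
- Problem sizes: analyses run at the cohort's n = 155; recovery tests use
  n = 5000, enough to make the 4σ/√n and 10% bounds sharp while keeping
  the suite fast.
- Schemas, criteria, thresholds, drinks and composition tables are YAML;
  responses are CSV (one row per respondent, empty cell = missing,
  `<item>__text` companion columns for free-text answers).
- The bundled 145-item FFQ and 36-item SDQ schemas are synthetic but
  structurally faithful — item counts, group coverage, unit mix and the
  free-text slots match the instruments' structure; item wording does
  not reproduce any copyrighted questionnaire.
- CLI exit codes: 0 success, 1 validation error, 2 I/O error; warnings
  (unmatched free text, missing groups, unpaired respondents) are counted
  per command and printed in its footer.

## Known limitations

- The energy route is used only for the discretionary group; total energy
  intake is not estimated, and nutrient-level intakes (lutein, omega-3)
  are out of scope.
- Exact band cut points of published 30-point criteria differ between
  instruments; results scored with the bundled default are comparable
  within this package, not across publications, unless the user supplies
  the matching criteria file.
- Agreement between two self-report instruments bounds neither's validity
  against weighed records; the statistics here quantify consistency, not
  truth.
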