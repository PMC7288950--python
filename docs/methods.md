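# Methods

## The scoring model

The package operationalises "immune status" as the position of eight
composite lymphocyte parameters relative to age-specific healthy
reference intervals. The composites are products of an absolute subset
count and a within-subset fraction,

- CD4 count × IFN-γ+CD4 fraction, CD8 count × IFN-γ+CD8 fraction,
  NK count × IFN-γ+NK fraction (functional cell numbers),
- CD4 count × CD28+/HLA-DR+/CD45RO+ CD4 fractions and CD8 count ×
  CD28+/HLA-DR+ CD8 fractions (phenotype-positive cell numbers),

all in cells per volume (per-millilitre in the bundled table; the unit is
carried opaquely from the input and never converted — the score is
unit-invariant as long as cohort and table agree). Fractions enter as
`pct / 100`; a composite therefore can never exceed its parent count, and
B cells contribute a count but no composite (no functional readout is
measured for them).

Each composite is assigned a tier in {−2 … +2} by comparing it with
0.5·L, L, U and 1.5·U, where [L, U] is the subject's age-group reference
interval; the tiers sum to a total in [−16, +16] and the total's sign
classifies the subject (hyperimmune > 0, hypoimmune < 0, normal = 0).
The tier structure deliberately mirrors organ-failure severity scoring:
small integer contributions per system, summed.

Boundary conventions (the interval wording leaves them open): "within
the interval" is closed, so x = L and x = U score 0; the extreme tiers
require strict inequality (x > 1.5·U, x < 0.5·L); the ±1 bands absorb
the remaining cut points, so x = 1.5·U scores +1 and x = 0.5·L scores −1.
If L = 0 (possible in user-built tables, not in the bundled one) the −1
and −2 bands are empty and any x ≤ U scores 0. Scoring is monotone in
each composite by construction.

## Age stratification

Four groups: children 1–5, adolescents 6–17, adults 18–65, elders ≥66
years. Ages are floored to whole years before assignment; the printed
group definitions of the source cohort overlap at 18, and 18 is resolved
to *adults* (the eldest stratum's observed range begins at 66, and an
18-year-old must belong to exactly one group). Ages below 1 year are
outside the model's domain and rejected at ingest.

## Reference intervals

Intervals are nonparametric: the empirical 2.5th and 97.5th percentiles
of the healthy stratum, with linear interpolation between order
statistics at position `p(n−1)+1` — the default "linear" rule of
mainstream numerical stacks, chosen for reproducibility; an independent
sort-and-interpolate oracle in the test suite pins the definition.
No outlier pre-filtering and no parametric (Gaussian/Box–Cox)
alternative is offered. Strata with fewer than 40 observations produce a
warning (nonparametric limits need substantial n; CLSI-style guidance)
but still return a result; strata with fewer than 2 values are omitted.
Sex stratification is available (`adults/female`-style strata) but off
by default: in the source cohort most parameters showed no material sex
difference.

The bundled table (`paper_tables_1_2`) transcribes the per-age-group
"mean ± SD (2.5%–97.5%)" cells of a published 261-subject healthy cohort
(47/72/90/52 per group) for all 12 measured and 8 composite parameters,
verbatim including its internal rounding quirks. A transcription test
compares it cell-by-cell against an independently typed copy. Tables
serialize to a versioned JSON document; values round-trip as decimal
text, bit-exactly.

## Synthetic cohorts

No subject-level data accompany the bundled table, so the generator
stands in for them:

- Ages are uniform within each group's bounds (children [1, 6),
  adolescents [6, 18), adults [18, 66), elders [66, 83)); group sizes
  default to 47/72/90/52 and sex ratios to the source cohort's. An
  `age_range` override draws n subjects uniform over a given span, e.g.
  59 controls aged 23–76 to emulate an age-matched control pool.
- Each measured parameter is drawn from a normal with the group's mean
  and SD, truncated to its support — counts on [0, ∞), percentages on
  [0, 100] — via inverse-CDF on uniform draws, so cohorts are exactly
  reproducible from the seed. True truncation (not clipping) is used for
  both supports: clipping would place a point mass at 100 for
  high-expression markers such as CD28+CD4+ (group mean 98.17, SD 4.03)
  and break the 95% coverage property of intervals estimated from
  generated data.
- Parameters are independent given age. All cross-parameter correlation
  is carried by the age trend: with `age_trend=True`, means and SDs are
  piecewise-linear in age through the groups' observed mean ages (3.81,
  10.81, 46, 71.04 years; flat beyond the outer knots), which reproduces
  the qualitative lifespan directions — CD4/CD8/B counts fall, NK count
  rises, all three IFN-γ+ fractions rise, CD28+ fractions fall,
  HLA-DR+/CD45RO+ fractions rise — with rank correlations significant at
  n = 1,000.
- Patient cohorts are healthy draws with multiplicative shifts applied
  before derivation, re-clipped to the support. Defaults: hypoimmune =
  all four counts × 0.4; hyperimmune = the three IFN-γ+ fractions plus
  HLA-DR+CD4/CD45RO+CD4/HLA-DR+CD8 fractions × 1.6 (capped at 100).
  These are calibration devices that push score distributions to the
  expected side of zero, not disease models.
- `match_controls` is uniform under-sampling without replacement
  (count or fraction), mirroring the random under-sampling used to
  balance control and patient group sizes.

**What passing synthetic tests does and does not show.** The generator
matches the healthy cohort's first two moments per parameter and group,
the supports, and the direction of every age trend. It does not model
the skewness of real immunological data (counts are approximately
log-normal; the published intervals sit asymmetrically around their
means), nor within-age correlation between a count and its fractions.
Two visible consequences, measured by the test suite and the
reproduction script: composite SDs under independence exceed the
published composite SDs (e.g. CD28+CD8+ number in adults: ~123 vs 98),
and healthy cohorts scored against the *bundled* table centre slightly
below zero (grand mean total ≈ −0.5 at the 59-subject control design,
because a symmetric generator puts more than 2.5% of its mass below a
right-skewed interval's lower limit). Scored against a table built from
the generator's own distribution, healthy cohorts centre within ±0.3 of
zero and ~95% of individual tiers are 0 — the self-consistent form of
the calibration property.

## Diagnostic evaluation

The two classification rules are one-sided and share one control group:
sensitivity for the hyperimmune rule is the fraction of cases with
total > 0; a control counts against its specificity only when *its*
total > 0 (mirrored for the hypoimmune rule with total < 0). This
one-sided reading is what the cutoff definitions literally say, and it
is the only reading under which both specificities can be 100% against
a shared control group in which some controls may deviate in one
direction.

Descriptive statistics use Spearman rank correlation (midranks for
ties, two-sided p) and the two-sided Mann–Whitney U test — exact null
enumeration when both groups have ≤ 20 observations and the pooled
sample is tie-free, otherwise the tie-corrected normal approximation
with continuity correction. Both are pinned against brute-force
enumeration oracles on small inputs in the test suite.

## Problem sizes and numerical choices

- Reference-interval recovery and coverage tests use 10,000 subjects per
  group, with held-out coverage measured on a fresh 10,000-subject
  cohort; recovery is asserted on the probability scale (generator CDF
  at the estimated limits within 0.025/0.975 ± 0.0065, about 4 standard
  errors), which unlike relative error stays meaningful when a true
  2.5th percentile lies near zero.
- The control-calibration experiment (`immunoscore.reproduce`) uses 200
  replicates of 59 subjects, the control-arm size of the original study
  design, and reports the grand mean total score.
- Stochastic direction checks pool five cohorts of 100 patients so the
  median of the discrete total-score distribution is estimated stably.
- Output formatting is fixed (ages/counts/composites to 2 decimals,
  percentages/fractions to 4) so identical runs are byte-identical.

## Known limitations

- The model consumes numeric flow-cytometry summaries; gating,
  compensation and FCS parsing are out of scope, as are CD45RA (an
  isoform redundant with CD45RO for this purpose) and B-cell function.
- The bundled intervals come from a single-centre cohort; scoring
  subjects from other populations or instruments against it inherits
  that cohort's biases. Building a local table is the supported remedy.
- Tier cut multipliers (0.5×, 1.5×) and the sign-of-total classification
  are fixed by the model definition; no ROC optimisation over
  alternative cutoffs is provided.
- A reduced score over a subset of the eight composites (e.g. the three
  number×function products) is supported mechanically, but no default
  subset is recommended.
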