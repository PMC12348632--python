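# Methods

## The counting analysis

Each respondent answers one full-profile best-worst task over the six
QOL attributes (spiritual well-being, food security, health care,
social connections, economic opportunity, community assets). The
analysis is purely counting-based: no utilities are estimated from the
real data. For attribute *j*, `bw_j = B_j - W_j`; since every valid
respondent contributes exactly one best and one worst, `sum_j bw_j = 0`
always. Mean scores divide by the number of valid respondents and are
bounded in [-1, 1].

**Normalized relative weights.** The published weight column is not
accompanied by a formula; the min-shift share form

    w_j = 100 * (bw_j - min_k bw_k) / sum_k (bw_k - min_k bw_k)

regenerates all six published weights exactly from the published B-W
column (shifted scores 138, 104, 135, 0, 125, 38; sum 540) and is
adopted as canonical. The least-preferred attribute scores exactly 0;
rounded weights sum to 100 up to half-ulp accumulation (the published
column sums to 100.01). If all scores are equal the weights degenerate
to the uniform 100/J.

**Ranking.** Rank 1 is the largest `bw`; ties break by best count
descending, then declared attribute order. Sorting by `bw`, mean, or
weight yields the same permutation (they are monotone transforms).

**Friedman test.** A single best/worst pick induces only a partial
order, completed by tie-averaged mid-ranks: best = 1, worst = J,
everything else (J+1)/2. The statistic uses the general tie-corrected
form `(J-1) * sum_j (R_j - n(J+1)/2)^2 / (A - C)` with `A` the sum of
squared ranks and `C = n J (J+1)^2 / 4`; for this rank pattern it
reduces to `2.5 * sum_j bw_j^2 / n`. The implementation is checked in
the tests against an independently coded classical formula and against
scipy's Friedman test. The published statistic (24.11) cannot be
reproduced or checked without respondent-level data: on implied ranks
the statistic is a deterministic function of the published margins and
evaluates to 194.3, so the published value must have been computed on
some other ranking basis that the source does not specify.

## Identification stage

Descriptive tables follow the published table's own (mixed)
conventions, exposed explicitly rather than hidden:

- gender: percentages over the 208 respondents who answered (2 dp);
- age: over all 217 rows including "PNR or missing" (2 dp);
- race, education, relationship, employment: over all 217 rows at 1 dp
  (the published cells are zero-padded, e.g. 61.30 = round1(133/217)).

All rounding is half-away-from-zero (percentages to the per-variable
precision above; mean scores to 3 dp). Three cells of the published
table are internally inconsistent and are reproduced as computed, with
the discrepancy documented rather than imitated:

1. the male share prints 40.39 but 84/208 = 40.38 under any rounding;
2. the relationship rows sum to 207, not the 217 the percentages use
   (hence `DescriptiveTable` accepts an explicit denominator override);
3. the mean B-W for health care (0.207) and community assets (-0.239)
   correspond to dividing by ~217, while the other four rows match the
   stated n = 213. The package always divides by the cleaned n.

**Sampling design.** The proportion formula `n = ceil(z^2 p(1-p)/e^2)`
(the exact content of the cited sample-size reference is not printed;
the standard normal-approximation form is assumed) gives n = 267 at
p = 0.5, 95% confidence, 6% margin — below the 280 completed
interviews — and the margin achieved by 213 valid responses is
z*sqrt(0.25/213) = 0.0671, "slightly" above the 6% design target.
The "dimension reduction" mentioned for this stage has no specified
procedure or reported result and is out of scope.

## Cleaning

Records are removed for exactly one reason each, tested in a fixed
order so the report is a partition: missing best/worst (incomplete),
unknown attribute token, best = worst (contradictory), duplicate
respondent id (first occurrence kept). Demographic non-response (the
`PNR` sentinel) is never grounds for removal — it is a first-class
reporting category, excluded only from segment-level inference.
Cleaning is idempotent and `n_raw = n_valid + sum(removed)` holds for
every input.

## Segmentation stage

Segments are the non-PNR categories of one demographic variable after
the schema's merge map (young adults fold into adults, mirroring the
survey's own handling of its 5 young-adult respondents); the default
minimum segment size is 10. The contrast is a chi-square test of
independence on the segment × best-choice table without continuity
correction; attributes never chosen drop out (df adjusts) and a flag
marks expected cells below 5. Best counts are used because they are
non-negative integers with fixed margins — B-W scores are not valid
chi-square inputs; a worst-choice basis is available behind a flag. The
published chi-squares (16.925, 2.74, 49.760, 46.502, 48.478) are not
reproducible: the source does not state what table or df each was
computed on. The implementation is validated instead by construction
(scipy's test on the same table), by null calibration (type-I error at
the nominal 5% within binomial error over 500 simulations), and by
power that rises monotonically with an injected segment utility shift.
No multiple-testing correction is applied across the six variables,
matching the source analysis; a Bonferroni helper exists but is off by
default. Significance labels: `**` p<0.01, `*` p<0.05, `.` p<0.10.

## Characterization stage

Personas are structured data, not prose: the score table of the
records matching a conjunction of demographic selectors, summarized as
top attribute, secondary attribute, and the bottom-two attributes, with
the templated name `<Top attribute> Focused <descriptor>`. Construction
is a pure function of (dataset, rule); under-supported rules are
skipped with their match count. "Educated" maps to bachelor's/master's+
and "low education" to some-college/high-school/some-high-school
(associate's sits in neither); both are configurable. The default rule
set encodes the four published archetypes: retired-married-female,
full-time-single-male, full-time-single-female with low education, and
unemployed-single with low education.

## The synthetic generator

**What it emulates.** Choices follow a sequential best-then-worst
softmax (maxdiff with Gumbel noise): best ∝ exp(u) over all attributes,
then worst ∝ exp(-u) over the rest. Demographics are drawn
independently per variable from the published category margins.
Respondent utilities are a base profile plus the additive shifts of
every matching segment spec. Response errors are injectable (blank the
worst pick, or overwrite it with the best pick) and every manipulation
is recorded in a ground-truth sidecar so cleaning reports reconcile
label-for-label. One root seed; respondent *i* uses the substream
`default_rng((seed, i))`, making records reproducible in isolation and
datasets byte-identical across runs.

**The paper-like preset.** Base utilities are moment-matched so the
mixture's expected best shares equal the published best frequencies
over n = 213 exactly (a 5-parameter fit to 6 shares on the simplex,
solved by Nelder-Mead least squares). The worst shares then carry no
remaining freedom: a single utility dimension cannot also reproduce the
published worst column, whose pattern is polarized (spiritual
well-being drew the most best picks *and* the second-most worst picks).
The model-implied worst shares therefore differ from the published ones
(e.g. 0.034 vs 0.103 for spiritual well-being), and the preset's
expected B-W ordering — spiritual > economic > health > food > social
> community — swaps two near-tied published pairs (health/economic at
expected B-W 41.9 vs 42.1, social/community). Segment shifts reproduce
the published subgroup contrasts qualitatively (women toward spiritual
well-being and health care, men and full-timers toward economic
opportunity, retirees and older bands toward spiritual well-being, the
unemployed and lower-educated toward food security and community
assets, singles toward economic opportunity and social connections);
their magnitudes were calibrated once so that each of the four default
persona cells has its documented top attribute by expected B-W with a
clear margin (the thinnest, the working single low-education female
cell, leads on health care by 0.113 expected B-W per respondent), and
are versioned constants in `simulate.py`.

**What passing tests do and do not show.** The generator reproduces
the published margins and first-moment structure, not respondent
heterogeneity (no mixed-logit taste variation, no intersectional
dependence between demographic variables, no nonresponse mechanism).
Results on synthetic data validate the pipeline's arithmetic and its
statistical calibration under this model, not substantive conclusions
about any real community.

**Rank recovery at the survey's scale.** At n = 213 the full sample
B-W ordering matches the generator's expected ordering in only ~51% of
draws. This is a property of the published effect sizes, not of the
implementation: with expected shares pinned to the published table,
the health-care/economic-opportunity pair differs by ~0.2 expected B-W
against a standard deviation of ~12, so that single pair flips in
roughly half of all samples (the published gap itself, 45 vs 35, is
under one standard deviation). Full-order recovery at this sample size
would require effect spacings the survey's own data do not exhibit.
The well-separated extremes (spiritual well-being on top, social
connections/community assets at the bottom) recover essentially
always; with well-separated utilities the ordering is recovered
exactly at n = 20,000 in the consistency tests.

## Problem sizes and numerical choices

Simulation-based checks use: 500 replicates at n = 500 for chi-square
null calibration (expected cells stay ≥ 5 there, keeping the
asymptotic reference valid at the smallest cell, community assets ×
male); 3 shift levels × 200 replicates at n = 213 for power; 200 seeds
at n = 213 for rank recovery; 2,000 records for cleaning-label
reconciliation; 60,000 records for the persona demonstration so the
thinnest persona cell holds ~750 respondents (~3.5 SD of safety).
Rounding is half-away-from-zero throughout, implemented in decimal
arithmetic on the shortest float repr. The softmax is computed
max-shifted; categorical draws use inverse-CDF on cumulative sums.
Degenerate inputs have defined behavior: empty analysis sets,
single-segment tables, all-equal score vectors, and zero denominators
raise typed errors or return documented degenerate values rather than
propagating NaNs.
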