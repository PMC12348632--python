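# qolbws — best-worst scaling analysis of community quality-of-life priorities

`qolbws` implements the counting analysis for single-task, full-profile
best-worst scaling (MaxDiff) surveys together with the three-stage ISAC
procedure — **I**dentification, **S**egmentation, **C**haracterization —
used to profile how demographic subgroups of a community prioritize the
factors that make up their quality of life (QOL). It was built around a
telephone survey of low-income Guilford County (NC) residents in which
each respondent saw six QOL attributes at once — spiritual well-being,
food security, health care, social connections, economic opportunity,
community assets — and picked the most and the least important one.
The survey's respondent-level data are not public; the package therefore
ships a synthetic respondent generator with the survey's published
demographic margins and choice frequencies as its defaults, so every
stage of the pipeline is testable end to end.

It is aimed at survey statisticians and community-health researchers who
want a small, fully tested reference implementation of the BWS counting
workflow rather than a model-based (multinomial-logit / hierarchical
Bayes) MaxDiff estimator.

## The statistics

For attribute *j* over *n* valid respondents, with best-pick count
*B<sub>j</sub>* and worst-pick count *W<sub>j</sub>*:

- **B−W score**: *bw<sub>j</sub> = B<sub>j</sub> − W<sub>j</sub>*
  (sums to zero across attributes);
- **mean B−W**: *bw<sub>j</sub> / n* ∈ [−1, 1];
- **normalized relative weight** (in %):
  100 · (*bw<sub>j</sub>* − min<sub>k</sub> *bw<sub>k</sub>*) /
  Σ<sub>k</sub>(*bw<sub>k</sub>* − min<sub>k</sub> *bw<sub>k</sub>*),
  so the least-preferred attribute scores exactly 0;
- a **Friedman test** (tie-corrected) on the within-respondent ranks
  implied by a single best/worst pick: best = 1, worst = *J*, the other
  *J* − 2 attributes share the mid-rank (*J* + 1)/2;
- **segmentation**: per-subgroup score tables plus a chi-square test of
  independence on the subgroup × best-choice contingency table;
- **characterization**: deterministic personas — the score table of the
  records matching a conjunction of demographic selectors, summarized as
  top / secondary / lowest-priority attributes.

The synthetic generator draws demographics from categorical marginals
and choices from a sequential best-then-worst softmax model with
segment-dependent utility shifts; corruption (incomplete or
contradictory answers) is injectable and fully labelled.

## Worked example

```bash
qolbws simulate --n 280 --seed 7 --incomplete-rate 0.15 \
       --contradictory-rate 0.09 -o out/sim
qolbws analyze out/sim/dataset.csv -o out/analysis
```

or, through the library, the numbered drivers under `analysis/`
(`01_simulate.py` … `05_personas.py`). Running them prints, among other
things, the published score table recomputed from its frequency
columns:

```
  1. Spiritual Well-being   B-W   48  mean   0.225  weight  25.56%
  2. Health Care            B-W   45  mean   0.211  weight  25.00%
  3. Economic Opportunity   B-W   35  mean   0.164  weight  23.15%
  4. Food Security          B-W   14  mean   0.066  weight  19.26%
  5. Community Assets       B-W  -52  mean  -0.244  weight   7.04%
  6. Social Connections     B-W  -90  mean  -0.423  weight   0.00%
```

— spiritual well-being carries the largest relative weight, food
security a moderate one, and social connections anchors the scale at
zero — and the cleaning/segmentation/persona stages on the simulated
survey, e.g.:

```
cleaning: 280 -> 215 valid ({'incomplete_choice': 39, ...})
design: n=267 needed at 95%/6% (<= 280 completed); achieved margin at n=215: 0.0668
  Spiritual Well-being Focused Retired Female (n=4134): top=spiritual, ...
  Food Security Focused Unemployed Single (n=54): top=food, ...
```

Outputs land as CSV/JSON/Markdown under `results/` (or the `-o`
directory for the CLI): `table1.csv` (descriptives), `table2.csv`
(scores), `segments/<variable>.csv`, `comparisons.json`,
`personas.json`, `cleaning_report.json`, `report.md`.

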