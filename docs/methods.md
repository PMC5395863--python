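# Methods

## The procedure

For each systematic review in a corpus, the unit of analysis is the
review's *primary* meta-analysis: one summary measure (RR, OR, RD, MD or
SMD), one model (fixed or random effects), one pooling method
(inverse-variance or Mantel–Haenszel), and the list of included studies,
each tagged with any of three grey-literature labels (non-English,
unpublished, dissertation). For every label carried by at least one
included study, the meta-analysis is recomputed on the studies *not*
carrying the label, with the identical measure/model/method. Reviews with
no study of a type are skipped for that type, mirroring the selection of
an analysis set of "reviews that included the type".

The with/without comparison yields: percent of studies and of participants
lost; percent change in the point estimate,
`100·|θ̂_without − θ̂_with| / |θ̂_with|`, and in the 95% CI width,
`100·|w_without − w_with| / w_with`, both computed on the **natural
(reported) scale** (widths of back-transformed intervals for ratio
measures, not log-scale widths — recomputing published example rows
confirms this is the scale on which such tables are built); a five-level
category; and a significance-flip flag.

### Classification

The percent change in the point estimate is rounded to the nearest integer
(half away from zero) and mapped: 0–4 negligible, 5–10 small, 11–20
moderate, ≥21 large. Integer rounding is what closes the otherwise
ambiguous 10–11% gap between the small and moderate bands, and it
reproduces the published convention (a 10.1% change labelled "small").
*Substantial* is reserved for the case where every included study carried
the excluded label, so no reduced estimate exists at all; an exclusion
whose reduced set is non-empty can never be substantial. A percent change
with a zero denominator (reference point estimate exactly 0, or zero CI
width) is *not estimable* and maps to its own category.

### Significance flips

A pooled result is significant iff its 95% CI strictly excludes the
measure's null value (1 for RR/OR, 0 for RD/MD/SMD). A bound exactly on
the null counts as **not** significant — the convention used in published
narrations of such flips, where an interval reaching 0.00 is described as
no longer significant. Flips are `lost`, `gained` or `none`; if either
side is not estimable the flip is `undefined`.

## The meta-analysis engine

Effect sizes and pooling follow the conventions of the standard
review-production software:

- **RR/OR** are analysed as log effects with the usual large-sample
  variances (`1/a − 1/n₁ + 1/c − 1/n₂` and `1/a + 1/b + 1/c + 1/d`).
  When any of the four cells is zero, 0.5 is added to *all four* cells of
  that study. Studies with zero events in both arms are not estimable on
  ratio scales and are dropped from inverse-variance pooling.
- **RD** uses the raw risk difference with binomial variance
  `p₁(1−p₁)/n₁ + p₂(1−p₂)/n₂`; a double-zero (or double-full) arm would
  give a zero variance term, so that term alone is computed with the
  shrunk proportion `(e + 0.5)/(n + 1)`, keeping the study poolable with
  an honest, positive variance.
- **MD** variance is `s₁²/n₁ + s₂²/n₂`. **SMD** is Hedges' g: the pooled-SD
  standardized difference times `J = 1 − 3/(4N − 9)`, with variance
  `N/(n₁n₂) + g²/(2(N − 3.94))`. (Other packages use the large-sample
  `g²/(2N)` term; the difference is third-decimal at realistic sizes. The
  correction can be inspected and switched off by computing the raw
  standardized difference `g/J`.)
- **Inverse-variance pooling** with fixed weights `1/vᵢ` or
  DerSimonian–Laird random weights `1/(vᵢ + τ²)`,
  `τ² = max(0, (Q − df)/C)`, `C = Σw − Σw²/Σw`. τ² is 0 for a single
  study. DL is the only τ² estimator offered: it is the default of the
  software the original analyses were run in, and exposing alternatives
  would invite silent method mismatches in re-analysis.
- **Mantel–Haenszel** fixed-effect pooling for dichotomous outcomes with
  the Greenland–Robins variances for log RR and log OR and the classic
  MH-weight variance for RD. Zero-cell studies need no correction (they
  contribute through the sums); if every stratum is uninformative the
  result is flagged not estimable. A review declaring MH with a *random*
  model, or carrying precomputed effects, falls back to DL
  inverse-variance pooling — the behaviour of the review software, which
  layers DL on top of its dichotomous defaults. The engine's DL and MH
  RR/OR results are cross-validated against R's `metafor` to 1e-9 in the
  test suite; for the MH RD variance `metafor` implements the Sato
  estimator, so only the point estimate is compared there.

An empty or all-unestimable study list yields a *flagged* not-estimable
result rather than an exception: the substantial category requires
representing "no estimate exists" as a value.

95% CIs use the normal quantile 1.959963984540054 throughout (`±1.96·SE`
on the analysis scale, exponentiated for ratio measures). Reporting rounds
estimates to 2 decimals and percentages to 1 decimal, half away from zero;
all internal computation is full precision.

## The reference tables

The package ships two small CSVs: 32 published with/without sensitivity
re-analysis rows (15 non-English, 8 unpublished, 9 dissertation exclusions
from Cochrane child-health reviews) and the matching searching/inclusion
count table. They serve as fixed estimate-pair inputs for end-to-end
checks: feeding each row's reported pooled estimates through the
percent-change metrics reproduces the reported pair to one decimal for 23
of the 29 rows that have a reduced estimate, and the reported category for
every row that prints one.

The remaining cells are documented irreproducibilities of the source
tables, not of this implementation: the original analysts computed from
unrounded pooled values, so recomputation from the printed, rounded inputs
can differ in the last decimal (e.g. a point change of 30.6 vs a printed
30.7, 10.2 vs 10.1, 3.4 vs 3.5) and, for two CI-width cells, by more than
rounding can explain (2.2 vs 1.1 and 0.3 vs 3.5). One row prints a dash
for its point change where the computable value is 100%; this package
generalizes that case conservatively by treating only a *zero* reference
estimate as non-reportable. Two ratio-scale rows print no summary measure;
they are stored with the ratio measure implied by their estimates, which
affects no computed quantity. The count table likewise contains three
cells whose printed percentage disagrees with its own printed counts
(7.3 vs 5/55, 5.6 vs 8/124, 0.8 vs 6/238); `summarize` computes from
counts, and the tests pin the count-implied values for those cells.

The inclusion percentage uses reviews that *searched* for the type as its
denominator, and a review is counted as including a type only if it also
searched for it — the invariant `included ≤ searched` that the count
tables assume.

## The synthetic generator

`GeneratorConfig` defaults describe the emulated register:

| parameter | default | meaning |
|---|---|---|
| `n_reviews_per_group` | ARI 57, ID 38, DPLP 34 | reviews per review group |
| `studies_per_review` | NB(0.4, 0.0741) + 1 | median 3, quartiles ≈(1, 7), mean 6 |
| `label_prevalence` | 0.044 / 0.019 / 0.019 | non-English / unpublished / dissertation, per study |
| `searched_probability` | 0.992 / 0.961 / 0.217 | per review |
| `outcome_mix` | 0.6 | share of dichotomous-outcome reviews |
| `true_effect` | N(0, 0.3) | per-review effect, analysis scale |
| `between_study_sd` | 0.1 | within-review heterogeneity, analysis scale |
| `grey_effect_shift` | 0.0 | added to grey-labelled studies' effects |
| `baseline_risk` | 0.2 | control-arm risk, dichotomous outcomes |
| `arm_size_distribution` | logN(4.4, 1.0), min 10 | participants per arm; median review ≈600 participants |

The studies-per-review family deserves a note: the register being emulated
reports a median of 3 studies but also a total of 780 studies over 129
reviews (mean ≈ 6), and those two facts are incompatible with the very
wide interquartile range it also prints. The default matches the median
and the mean with a heavy-tailed negative binomial and exposes (r, p) in
config for anyone wanting a different tail.

Dichotomous studies draw arm sizes first, then events from the
effect-implied risks (`p₁ = p₀·e^θ` for RR, logit-shifted for OR), so arm
data are always internally consistent with the study's effect. Continuous
studies use a unit population SD, so MD and SMD share the effect scale;
sample means get `1/√n` noise and sample SDs a chi-squared draw.
Reviews draw measure (RR 80% / OR 20% of dichotomous; MD 60% / SMD 40% of
continuous), model (fixed/random 50:50) and method (MH for 30% of fixed
dichotomous reviews). RD is fully supported by the engine but not
generated by default — RD-pooled primary analyses are rare in the emulated
register. Labels are independent of effect size unless
`grey_effect_shift ≠ 0`, making the shift the single, explicit bias
mechanism. Participants per study and studies per review are generated
independently; any real joint structure (small reviews of small trials) is
not emulated.

What passing simulation checks therefore show: the pipeline is unbiased
under the null (no shift, no heterogeneity ⇒ negligible impact dominates)
and detects a directional bias when one is injected. They do not show that
real grey studies are biased, nor reproduce any specific review's data,
which are not available in machine-readable form.

Generation is fully driven by one `numpy` `default_rng(seed)`; identical
seeds give identical corpora and, through the deterministic writers,
byte-identical corpus files.

## Problem sizes

The simulation checks use 100-review corpora (≈600 studies) and 20
replicates for the directional test, sizes at which the tested effects are
decisive (the directional t-statistic is ≈20 against a threshold of 3)
while the full suite runs in seconds.

## Known limitations

- Heterogeneity inference stops at τ²: no Q-test p-values, I², prediction
  intervals, Peto OR or exact methods.
- One label at a time; joint exclusion of multiple grey types is out of
  scope, as is any inference (bootstrap CIs) on the change statistics.
- The generator does not simulate citation text, search strategies or
  screening, and its label assignment is marginal, not topic-dependent.
- Corpus files carry study-type labels as given; identifying non-English
  or dissertation status from citations is upstream curation, not
  computation.
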