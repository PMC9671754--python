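# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data results do and do not say
about real specimens.

## The mixture model behind the simulator

A cervicovaginal specimen is modelled as a two-component mixture of
epithelial and immune-cell DNA. For sample *i* and CpG *j*,

```
beta[i, j] = clip((1 − f_i)·epi_ij + f_i·imm_j + ε, 0, 1)
```

* `f_i` — the specimen's immune fraction, drawn Beta(2, 5) by default
  (mean ≈ 0.29, broad right-skewed spread; immune contamination varies
  hugely between specimens but most are epithelium-dominated). Both
  parameters are configurable.
* `imm_j`, and the baseline of `epi_ij` — per-CpG reference methylation
  levels. About 4% of CpGs are "discoverable": methylation below 0.1 in
  *both* compartments, arranged in clusters of 8 CpGs with 30–60 bp
  spacing (total span < 500 bp, the geometry a single qPCR amplicon needs).
  Background CpGs have independent uniform(0.05, 0.95) baselines and
  0.8–2 kb spacing, so discoverable clusters are never within clustering
  range of stray background sites.
* Planted cancer signal — for case samples only, and only in the
  epithelial term, `effect_size` (default 0.3) is added at the CpGs of
  `n_true_regions` (default 3) randomly chosen discoverable clusters.
  Confining the effect to the epithelial compartment reproduces the
  defining nuisance of this assay class: the observed case signal shrinks
  as the immune fraction grows. By default a planted region occupies a
  whole cluster; planting fewer CpGs than a cluster holds is allowed but
  then region recovery on exact coordinates is not expected, because
  discovery legitimately clusters the remaining eligible neighbours.
  `effect_size = 0` is a valid null simulation (regions are still chosen
  and reported, no signal is added) used for false-discovery checks.
* `ε` — additive Gaussian noise on the beta scale (default sd 0.05),
  clipped to [0, 1]. Chosen over a logit or beta-distributed model because
  it supports exact zero-noise identities, which anchor the deconvolution
  and round-trip tests.

Default cohort: 100 cases + 100 controls on 2,000 CpGs. These are the
package's reference study conditions for all recovery and null claims; the
genome-scale analogue (~850k sites) is the same algorithm at larger n.

What the simulator deliberately omits: array chemistry and probe-type
effects, batch effects, more than two cell compartments, age- or
menopause-dependent methylation drift, copy number, and any correlation
between noise at neighbouring CpGs. Passing tests therefore demonstrate
the correctness and internal consistency of the algorithms, not the
clinical performance of the markers on real specimens.

### qPCR simulation

Ground-truth PMR for a region is 100 × its mean beta (a fully methylated
calibrator corresponds to beta 1). Each sample draws a reference-assay Ct
uniformly in 24–32 cycles; each marker well gets
`Ct = ref_Ct − log2(PMR/100) + noise` with perfect doubling (efficiency
fixed at 2 — the standard MethyLight assumption; configurable at scoring
time). PMR 0 maps to an "Undetermined" well. DNA-insufficient specimens
(probability `dropout_rate`) get a reference Ct 1–5 cycles beyond the QC
limit and undetermined marker wells, so the QC path is exercised end to
end rather than via missing rows. The calibrator runs every assay at Ct 25
(target/reference ratio exactly 1), making the zero-noise round trip
`simulate → score` exact to floating-point precision.

## Discovery

**Immune fraction.** Least squares on the two-profile mixture: the
unconstrained minimiser of `||beta − ((1−f)·epi + f·imm)||²` is closed-form
(`f = ⟨imm−epi, beta−epi⟩ / ||imm−epi||²`) and is projected onto [0, 1].
Identical profiles make *f* unidentifiable and return NaN. On noise-free
exact mixtures the estimator is exact; the tests require < 0.05 absolute
error on a grid of fractions.

**CpG ranking.** For each CpG, a least-squares fit of
`beta ~ 1 + case + immune_fraction` over all samples, scored by the
t-statistic of the case indicator — a transparent, immune-adjusted
association score. Eligibility caps (both 0.2 by default) are applied to
the two compartment endpoints estimated from controls alone by regressing
beta on the immune fraction: the fit at fraction 0 is the control
epithelial methylation, at fraction 1 the immune-cell methylation. This
estimates both screening quantities from the screen itself rather than
requiring an external reference panel at ranking time. CpGs with identical
values in every sample carry no information; their statistic is forced to
0 rather than left to a ratio of rounding errors.

**Regions.** The top 30 ranked CpGs seed clusters of ranked CpGs within
±500 bp; clusters sharing members on a chromosome merge transitively;
clusters with < 3 members are dropped. Intervals are 0-based half-open
(BED semantics), spanning min to max member position + 1. Candidate
regions are scored per sample by mean beta over members (the array
surrogate of a MethyLight reaction) and ranked by empirical AUC, ties
broken by genomic order for determinism. The panel is the top 3.

## Scoring and QC

`Q(Ct) = E^(−Ct)`; undetermined → quantity 0. PMR as in the README; an
undetermined *calibrator target* is an assay failure (the fully methylated
control must amplify), whereas an undetermined *sample target* is simply
PMR 0. Replicate Cts are averaged; a mixed group (numeric + undetermined)
uses the numeric mean and logs a warning. A specimen is valid iff its
reference Ct is numeric and ≤ 38 cycles (boundary inclusive; the cutoff is
configurable — insufficient-DNA exclusion needs *some* fixed limit and 38
is a conventional late-cycle bound). PMR values above 100 are retained:
Σ PMR is a score, not a proportion, and capping would discard signal.
Σ PMR is the exact floating-point sum of the three PMRs.

## Thresholds

Candidate cutoffs are the midpoints between adjacent distinct development
scores plus sentinels below the minimum and above the maximum (realising
the all-positive and all-negative rules). With the `score ≥ cutoff ⇒
positive` convention, threshold 1 maximises specificity subject to
sensitivity ≥ 0.95 and threshold 2 maximises sensitivity subject to
specificity ≥ 0.95 (targets configurable); ties resolve toward the lower
cutoff. On a development set separable enough that the two constraint
regions overlap, the two optima can land in reversed order; the cutoffs
are then swapped so the high-sensitivity threshold sits lower, and the
swap is recorded in the provenance block. Negative sentinels are clamped
to 0, since Σ PMR is non-negative. Provenance (a hash of the development
scores, the rule parameters, cohort sizes) is persisted with the cutoffs
so a frozen test remains auditable. In the pipeline the development split
is the first 20 cases and 20 controls in cohort order — the synthetic
analogue of fixing thresholds in a small pilot set before validation.

## Evaluation

* Clopper–Pearson exact intervals via beta-distribution quantiles, with
  the closed-form boundary conventions (lower 0 at 0 successes, upper 1 at
  n successes). Chosen because the published bounds for 8/8 match the
  exact interval's closed form `0.025^(1/8)` exactly.
* PPV/NPV by Bayes' rule at an assumed prevalence (default 0.09, the
  symptomatic-setting assumption), with a sweep utility; PPV rises and NPV
  falls strictly in prevalence for any informative test.
* AUC by the pairwise definition (ties count ½), computed via mid-ranks;
  the ROC curve enumerates `score ≥ cutoff` operating points.
* DeLong's paired test with mid-rank placement values and empirical
  placement covariances; identical score vectors short-circuit to z = 0,
  p = 1, and a zero variance with unequal AUCs raises rather than
  fabricating a p-value. Mid-ranks matter here because comparator scores
  (mutation counts, mm thickness) are heavily tied.
* McNemar's exact two-sided test from binomial tails on the discordant
  pairs. The lead-time contrast (< 1 year vs ≥ 1 year to diagnosis)
  additionally reports a Fisher exact p-value, provided as a pragmatic
  stand-in since no particular test is canonical for that contrast.
* Report rounding: percentages to one decimal, PPV/NPV to the nearest
  integer percent.

## Reproducibility

One top-level seed; per-stage sub-seeds (all < 2³¹) derived through a seed
sequence. No artifact contains wall-clock metadata, so a rerun with the
same configuration and seed is byte-identical. Every writer's output is
re-readable by the package's own readers.

## Known limitations

* The discovery statistic and eligibility caps are principled but simple
  stand-ins; a production screen would consider moderated variance
  estimators, multi-compartment references, and batch structure.
* The two-compartment deconvolution is exactly the simulator's generative
  model; on real data, reference-based deconvolution error would propagate
  into the ranking in ways these tests cannot measure.
* Thresholds derived on a 40-sample synthetic pilot are stable only
  because the synthetic score separation is wide; small pilot sets on real
  data would give materially noisier cutoffs.
* Comparator modalities are simulated at plausible operating
  characteristics and support only machinery checks (pairing, ties,
  DeLong/McNemar plumbing), not claims about ultrasound or mutation
  testing.
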