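# Methods

## Scientific setting

Single neurons in the human medial temporal lobe (amygdala and hippocampus)
respond selectively to visual objects. This package implements an analysis
framework in which each stimulus is a point in a 2D feature space (a
normalized embedding of high-dimensional visual features), and a neuron is a
*feature neuron* when its responses are significantly elevated for stimuli
falling inside a contiguous region of that space — its *tuning region*.
Region coding generalizes classical category selectivity: a single-category
(SC) neuron corresponds to a narrow peak over one category cluster, a
feature-MC neuron to a single wide peak spanning several visually similar
categories, and a non-feature-MC neuron to multiple separate peaks. The
framework further links tuning regions to behavior: stimuli inside a
neuron's region are hypothesized to be better remembered in a recognition
task, and feature neurons to preferentially encode image memorability.

Because the recordings this analysis targets are not distributable, every
stage is exercised on a synthetic stated world with planted ground truth.

## Tuning-region detection

Per-stimulus responses `r_i` (mean firing rate 250–1250 ms post-onset, or
0–300 ms post-fixation for fixation-based analysis) are smoothed into a
density map over a 100×100 pixel grid on the unit square:

    D(p) = sum_i r_i * exp(-||p - x_i||^2 / (2 sigma^2))

with an isotropic Gaussian kernel of SD `sigma = sq` (in unit-square side
lengths). The published per-dataset scaling factors are exposed as presets
(0.021 for the 500-stimulus object set, 0.05 for the 500-stimulus
10-category set, 0.11 for the ~100-stimulus recognition-memory sets, 0.03
for the scene set); the rule that originally produced them (kernel size
proportional to cluster count and space dimension) is under-determined, so
`sq` is the single exposed knob. The unnormalized kernel sum is used rather
than a local average: the denominator of a local-average estimator is
permutation-invariant, so per-pixel permutation p-values are identical
either way.

The null distribution per pixel comes from shuffling responses across
stimulus coordinates (default 1000 permutations). The p-value uses the
add-one estimator `(1 + #{null >= observed}) / (1 + N)`, which cannot reach
zero and sends permutation-invariant (constant-response) neurons to p = 1
everywhere. Null maps equal to the observed map up to floating-point
summation order are counted as ties (a 1e-9 relative tolerance); without
this, a constant neuron can be spuriously flagged by last-ulp noise.

Pixels with p < 0.01 inside a mask are clustered (4-neighborhood by
default; 8 available) and clusters of at most 2.5% of the masked pixel
count are discarded. The mask removes edge and corner pixels whose center
is farther than `mask_radius_factor * sigma` (default factor 2) from every
stimulus; such pixels have no data support and are false-positive-prone. A
neuron with at least one surviving cluster is a feature neuron.

An optional cluster-level correction (`cluster_correction`, off by
default) replaces the fixed size floor with a permutation-derived one:
each null map is thresholded at its per-pixel (1 − pixel_alpha) null
quantile, the maximum suprathreshold cluster size is recorded per
permutation, and observed clusters must exceed the (1 − cluster_alpha)
quantile of that distribution. The headline selection uses the fixed
2.5% floor; the corrected mode exists as a robustness check.

Numerical notes: the kernel matrix (masked pixels × stimuli) is precomputed
once per feature space and shared across neurons and permutations, making
each detection a matrix product; stimulus-to-pixel assignment uses
half-open pixels `[i/R, (i+1)/R)`; region overlap between two regions is
`|A ∩ B| / min(|A|, |B|)` and population coverage is the union of
significant pixels over the mask.

## Category selectivity

A neuron is category-selective when a one-way ANOVA across categories on
response-window rates reaches p < 0.05 and at least one category's mean
response is ≥ 1.5 SD above the mean baseline (−500–0 ms) rate. Both
baseline statistics are computed across trials: with each image shown once,
trial-level SD is the only well-defined choice. One selected category makes
an SC neuron; several make an MC neuron. The MC subtype recomputes the
neuron's significant-pixel map *without* the minimum-cluster-size threshold
and asks whether all selected-category centroids fall in one connected
component (feature-MC) or not (non-feature-MC); this operationalizes
"categories clustered within the same region" and is an interpretation —
the original criterion is not fully specified.

Selectivity is quantified by d′ between the most- and least-preferred
categories, `(mu_best - mu_least) / sqrt((var_best + var_least)/2)` with
population variances (the n/n−1 distinction is negligible at these trial
counts), the depth-of-selectivity index
`DOS = (n - sum_j r_j / r_max) / (n - 1)` in [0, 1], and the response-ratio
curve (rates ranked and normalized by the best category). Degenerate inputs
(zero variance in both extreme categories, all-zero rates) return missing
values rather than infinities.

## Axis coding

The axis model tests whether responses follow a linear direction in
high-dimensional feature space: a partial-least-squares regression (10
components) is fit on a random half of the stimuli and scored as the
Pearson correlation between predicted and observed responses on the held
out half. The null distribution repeats this with shuffled responses
(default 1000 permutations); the model is significant when the observed
correlation exceeds the null 95th percentile. The observed statistic uses a
single split by default: observed and null statistics are then exchangeable
under the null, so the test is exactly calibrated at 5%. Averaging the
observed correlation over several splits (available via `n_splits`) reduces
split-to-split variance but makes the test conservative, and is therefore
not the default.

## Decoding

Neurons are pooled into a pseudo-population (trial × neuron × bin rate
tensor; 500 ms bins advanced by 50 ms, 31 bins from −500 ms). A
maximum-correlation classifier assigns each test trial to the class whose
training-mean template correlates best with the trial vector; ties and
zero-variance vectors resolve to the lowest class index. Stratified 8-fold
cross-validation (stratification prevents empty-class folds at small n;
the original partition was plain random) is repeated 50 times; per-neuron
z-scoring uses training-fold statistics only, applied to the test fold, to
avoid leakage. Per-bin significance against chance (1/n_classes) is the
fraction of repeats at or below chance, Benjamini–Hochberg corrected across
bins. Because all repeats reuse the same dataset, a noise bin whose data
happen to decode slightly above chance can be flagged; this is a property
of the published procedure, not of this implementation, and the tests
budget for at most a stray pre-onset flag.

## Recognition memory and memorability

Recognition trials use a 1–6 confidence scale (1 = new, very sure … 6 =
old, very sure); a hit is an old stimulus with response ≥ 4. Trials with
reaction times above 5 s or above the session mean + 3 SD are excluded
before scoring. Confidence is the mean response among old trials judged
old (range 4–6), configurable to all old trials; the original choice is not
stated. In/out-region comparisons pair each unit's (neuron's or session's)
in-region and out-region hit rates and confidences in two-tailed paired
t-tests, excluding sessions with hit rate ≤ 60%. Memorability analyses
compare top-30% vs bottom-30% memorability stimuli across sessions (only
sessions with > 10 trials in both groups), select memorability-coding
neurons by two-sided Pearson correlation (p < 0.05, both signs count), and
the matched comparison restricts out-region stimuli to memorability scores
within ±2 SD of the in-region mean. Cross-phase analysis asks whether
learning-phase regions predict recognition-phase responses (in vs out, for
all/old/new stimulus subsets) and flags invariant neurons at > 50% region
overlap.

Saccades are detected where instantaneous velocity exceeds 30°/s *or*
acceleration exceeds 8000°/s², sustained ≥ 4 ms with total deflection
> 0.1°; fixations are the complement. The per-sample OR (EyeLink-style)
is used because a strict AND would drop the constant-velocity middle of a
ballistic saccade and split one movement into two.

## Statistical conventions

The binomial excess test against the 5% chance level uses the STRICT upper
tail P(X > k). The inclusive tail P(X ≥ k) is what the usual textbook
definition prescribes, but the strict tail is the convention that
reproduces every published selection statistic this package mirrors from
its printed counts, so it is the default (inclusive available via flag).
Proportion comparisons use Pearson's chi-square, df = 1, no continuity
correction, on the 2×2 table laid out subpopulation-vs-whole (groups may
overlap). Tail probabilities go through scipy's incomplete-beta-based
routines, accurate to ~1e-300 — far below naive `1 - cdf` arithmetic.
FDR control is Benjamini–Hochberg. Paired and two-sample t-tests report
Cohen's d and a CI of the mean difference; all-zero-variance inputs return
a missing p-value instead of an infinite statistic.

One published value is not reproducible: the memorability-enrichment
chi-square on (31/116 vs 104/1162) is printed as below 1e-20, but both 2×2
layouts give on the order of 1e-8. The implementation computes the value it
computes; the discrepancy is documented here and not asserted anywhere.

## Synthetic stated world

The generator emulates the recorded setting, not any particular dataset:

- **Stimuli**: 50 categories × 10 exemplars (defaults). Category centroids
  uniform in the interior of the unit square, exemplars isotropic Gaussian
  with SD 0.03, coordinates min-max normalized. High-D features (128)
  embed the 2D coordinates through a seeded random rotation with small
  (0.02 SD) off-plane noise, so linear projections recover the 2D layout.
- **Neurons**: piecewise-homogeneous Poisson spiking — baseline 5 Hz
  outside the response epoch, and during 250–1250 ms post-onset the
  truth-implied rate: +gain·exp(−d²/2w²) for region neurons (gain 20 Hz,
  width 0.08), +gain·z(w·f) clipped at zero for axis neurons, +gain on
  selected categories for SC/MC neurons. Poisson is a choice (no noise
  model is implied by the setting); it makes rate recovery analytic.
- **Memory sessions**: half the stimuli learned (each shown once),
  recognition mixes old and new. For old stimuli
  P(judged old) = logistic(beta0 + beta_mem·memorability +
  beta_region·in_region) with beta0 = 1 (hit rate ≈ 0.73, typical of
  recognition performance above the 60% inclusion floor); false alarms at
  logistic(−beta0). Defaults beta_mem = beta_region = 0 (null world;
  effects are opt-in). Confidence within the chosen side tracks the model
  probability with unit Gaussian noise, clipped to 4–6 / 1–3. Memorability
  scores are Beta(4, 4) (unimodal on [0, 1], shape only). RTs are shifted
  lognormal (0.3 s shift, median ≈ 0.8 s), supporting the RT-outlier
  filter. One trial per stimulus by default (images were shown once).
- **Gaze**: piecewise-stationary fixations on object centers (0.02°
  jitter) joined by 10 ms linear ballistic saccades at 500 Hz, with the
  planted intervals returned for round-trip tests.

In tests the memory analyses plant the aggregated tuning region on an
actual category cluster (radius 0.3 around a random category centroid,
~15–30% of stimuli in-region): real tuning regions sit where objects are
and cover a minority of the space, and an in-region set divorced from the
stimulus distribution can be empty for some seeds.

What a green synthetic test does *not* establish: the generator has no
recording noise beyond Poisson variability, no spike-sorting artifacts, no
session-level drift, no correlated trial history (one-back repetitions are
out of scope), and features are a rotation of the embedding rather than a
deep network's representation — so recovery rates here are upper bounds on
what real recordings would give, and published neuron counts are not
reproduction targets.

## Scaled-down defaults in tests

Unit and acceptance tests run permutation procedures at 200 permutations
instead of 1000 (smallest attainable p-value 1/201 < 0.01, so the pixel
threshold is attainable and the add-one estimator is slightly *more*
conservative than at 1000 — extrapolation to 1000 only sharpens p-value
resolution, not the decision boundary) and decoding at 10–20 repeats
instead of 50. The 80-stimulus test world uses the kernel preset for
~100-stimulus spaces (sq = 0.11); the 500-stimulus world uses 0.021.

## Known limitations

- The feature-MC rule (all selected centroids in one connected component)
  is one operationalization of an under-specified criterion; neurons whose
  selection screen reaches farther than their significant blob are called
  non-feature-MC.
- The repeats-below-chance decoding significance inherits dataset-level
  luck (see above).
- t-SNE/UMAP reducers are delegated wholesale; only the `none` (identity
  normalization) and PCA paths are exercised in tests.
- The in/out paired t-test is mildly anticonservative (~1–2 points above
  nominal) when one group has very few old stimuli per session; the
  calibration tests measure this directly.
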