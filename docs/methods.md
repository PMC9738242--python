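# Methods

`wristbow` implements a passive-monitoring analysis pipeline that separates
Parkinson's disease (PD) from healthy elderly (HE) subjects using week-long
wrist accelerometry, together with a synthetic cohort generator that stands in
for clinical recordings.  This note documents the models, the parameters that
matter, the numerical choices, and what the synthetic experiments do and do
not establish.

## Signal model of the synthetic cohort

Each subject's tri-axial signal (g units, device axes) is

    a(t) = g_vec + movement(t) + tremor(t) + noise(t),  clipped to ±8 g

* **Gravity** `g_vec` is a fixed unit vector with a per-subject random tilt
  (SD 0.15 rad).  Features must therefore work under arbitrary device
  orientation; none of the descriptors assume a known "up".
* **Activity/rest bouts** alternate with exponential durations (defaults:
  means 60 s active / 90 s rest), a two-state Markov structure.  Each active
  bout is assigned one of four *activity types* drawn from a subject-specific
  Dirichlet mixture (concentration 0.6).  Types differ in spectral bandwidth
  (low-pass cutoffs 1.0/2.0/3.5/5.5 Hz) and intensity (×0.5/1.0/1.6/2.4);
  in-bout movement is variance-compensated low-pass-filtered Gaussian noise
  further scaled by a per-bout lognormal factor (SD 0.3), a per-day lognormal
  factor (SD 0.3) and the subject's `activity_scale`.
  The type mixture is deliberately high-variance and disease-unrelated: a
  subject's week-level descriptor *means* are dominated by lifestyle, which is
  the regime in which distribution-aware (bag-of-words) features have room to
  beat averaged features.
* **Rest-bout oscillation episodes.**  With per-bout probability
  `tremor_rate`, a rest bout carries a sinusoid at `tremor_freq_hz` with a
  random phase, a random 3-D direction, and a slow lognormal amplitude
  modulation (tremor waxes and wanes within an episode).  Both groups have
  episodes at comparable rates (HE 0.30, PD 0.35): healthy
  fidgeting/physiological oscillation versus pathological rest tremor.  What
  separates the groups is the episode *amplitude* (HE 0.035 g vs PD 0.10 g,
  i.e. roughly 3×) and a modest global movement reduction in PD
  (`activity_scale` 0.9) modelling bradykinesia.  PD tremor frequency is
  jittered within the 4–6 Hz band.
* **Heterogeneity.**  Per subject: `activity_scale` ×lognormal(SD 0.3),
  episode amplitude ×lognormal(SD 0.5), episode rate ±0.12 (uniform), tremor
  frequency ±0.8 Hz.  The groups consequently overlap subject-for-subject and
  classification stays well below ceiling, as in real cohorts.
* **Sensor model**: additive white noise (SD 0.02 g) and clipping at ±8 g; no
  quantization (nothing downstream is sensitive to it).

Randomness is split into independent SeedSequence streams (orientation /
bout layout / movement / tremor / noise), so changing one parameter — e.g.
tremor amplitude — does not reshuffle unrelated draws; cohorts are
bit-reproducible from `(config, master_seed)`.

**Null cohorts** give the PD group the HE phenotype exactly (labels become
pure noise); they are the pipeline's leakage/optimism control.

## Scales: desk vs full

Full-scale recordings (60 subjects × 7 days × 86 400 s × 100 Hz) are ~10^10
samples and are not a desk-scale object.  The `desk` preset compresses a
"day" to 1800 s at 32 Hz and scales the five window lengths eightfold
({0.375, 1.25, 7.5, 37.5, 112.5} s instead of {3, 10, 60, 300, 900} s).  The
eightfold (not 48-fold) window scaling is deliberate: at 32 Hz the shortest
window still spans ~2 cycles of a 5-Hz tremor and 12 samples, preserving the
physiological meaning of the short-window strategies; windows remain well
inside a compressed day so the multi-scale count structure survives.  The
`full_scale` preset keeps the original windows, 100 Hz and 86 400-s days for
full-scale runs.  Tests and the acceptance script state their problem sizes
explicitly; heavy simulation checks run at 2–4 day units and/or shortened day
units (600–1800 s) with the cohort design (32 HE + 28 PD) retained.

## Segmentation

Windows of length S overlap by S/2; a recording of duration t yields
floor(2t/S) − 1 complete windows (trailing partial windows are dropped —
every descriptor assumes a complete window).  Indices are 0-based and blocks
half-open.  The closed form is verified against direct enumeration on
non-divisible (t, S) grids.

## Descriptors (SDS)

Ten values per window: mean vector magnitude; per-axis normalized RMS
(components' squares sum to 1); per-axis movement dispersion; per-axis range.
Choices that were genuinely open:

* z-scores inside dispersion use the population (n-denominator) SD within the
  window; the alternative (n−1) changes values by O(1/n) and nothing
  downstream at realistic window lengths.
* The outlier rule removes a sample from the valid set of *all* axes when
  |z| > 2 on *any* axis.
* Degenerate windows: a zero-variance axis has z ≡ 0 (dispersion 0); fewer
  than two valid samples gives dispersion 0; an all-zero window has no RMS
  direction and yields a flagged null (NaN) descriptor that is excluded from
  subject averages and rejected at encoding time.  Returning 0 rather than
  failing keeps near-constant rest windows — common and informative — in the
  data.
* Dispersion is computed for all windows, not only gait/active ones.
* The dispersion pair sum uses the sorted prefix-sum identity
  Σ_{i<j}(v_(j) − v_(i)) = Σ_j (2j − m + 1) v_(j) (O(m log m)); an O(m²)
  pair-enumeration oracle exists solely for testing and agrees to 1e−9.
* `vector_magnitude` is the mean per-sample magnitude; the Euclidean norm of
  the three per-axis RMS values is a distinct quantity that appears only as
  the RMS normalizer.  Both exist under distinct names.

Statistical features: per window size, the unweighted mean of each descriptor
over the subject's windows (nulls excluded); concatenation over the five
sizes gives 50 features per subject.

## Bag of words

Per windowing strategy, all subjects' descriptors are pooled, standardized
(mean/SD of the building set — the 10 components mix g and z-units, so raw
Euclidean distance would be dominated by one component), and clustered with
PAM K-medoids.  The dissimilarity is squared standardized Euclidean distance;
the PAM objective, the WCSS reported on the k-curve and the exhaustive-search
test oracle are the same quantity, so "optimal" means one thing.

* CLARA-style scaling: PAM runs on a seeded subsample (desk default 2000
  points, 2 restarts; the full-scale preset uses 20 000/5).  Every pooled
  descriptor is then assigned to its nearest medoid and the full-data WCSS is
  what enters the elbow curve.
* PAM itself is greedy BUILD + steepest-descent SWAP; optional seeded random
  restarts keep the best objective.  On tiny instances (n ≤ 8) multi-start
  PAM attains the enumerated global optimum.
* k is chosen over candidates {4, 8, …, 32} (desk mini-preset: {2, 4, 8, 12,
  16}) by an automated elbow: the candidate maximizing perpendicular distance
  to the chord joining the curve's endpoints, ties toward smaller k.  An
  increasing WCSS curve is treated as a clustering-instability error.
* Encoding maps each window to its nearest medoid (standardized metric from
  the vocabulary) and the subject becomes term frequencies (counts/total), a
  probability vector per strategy; strategies concatenate in ascending window
  order.
* Two vocabulary scopes are first class: `cohort` (built on everyone —
  faithful to the original protocol, which leaks held-out subjects into the
  vocabulary) and `leak-free` (rebuilt inside each training fold;
  vocabularies verifiably depend only on training subjects).  Experiments
  record which scope produced them.

## Classification and feature selection

Six classifiers (RBF-SVM, Gaussian NB, decision tree, random forest 100
trees, 5-NN, AdaBoost), each behind a StandardScaler pipeline with pinned
hyperparameters (library defaults unless stated).  Evaluation: 100 runs
(tests scale this down) of shuffled stratified 10-fold CV; per run, accuracy
is pooled over held-out predictions and AUC comes from pooled decision
scores; arrays of per-run values are the unit of all downstream statistics.
Stratification is the default (a plain-split option exists); everything is
deterministic given the experiment seed.

GA feature selection evolves binary masks: population 40, 50 generations, 20
parents (10 fittest + 10 random), 4 uniform crossovers of random parent
pairs, 14 % per-individual mutation chance (bit flips at rate max(1/d, 0.05)),
next generation = {best} ∪ offspring ∪ mutated parents ∪ fresh random
individuals.  The fitness of a mask is the mean CV accuracy over a
configurable classifier set minus λ·(selected/total), λ = 0.05, with ties
broken toward fewer features; fitness values are memoized per mask.  Elitism
(carrying the best individual) makes the best-so-far trace non-decreasing —
a deliberate design choice so the returned optimum is monotone.  The
standard protocol selects features on the full cohort (as the original
analysis did — a known selection leak); `nested_ga_cv` provides the unbiased
variant with selection rerun inside every training fold.

## Statistical comparisons

* Windowing strategies: Shapiro–Wilk per group, one-way ANOVA, Tukey HSD at
  95 %.
* Feature methods: one-sided paired t-test (words > statistics) on
  (classifier, run)-aligned accuracies; a Welch two-sample variant is always
  reported alongside because the pairing protocol across 6 classifiers × runs
  is a design choice, not a fact of the data.  The all-differences-zero
  degenerate case is defined as t = 0, p = 0.5.
* Amount of data: recordings truncated to 1..7 day units; the full word
  pipeline (vocabularies included) is rebuilt per day count — the vocabulary
  is part of the estimator, so it must not see the longer recordings.
  Shapiro–Wilk and Levene gates (α = 0.05) pick ANOVA+Tukey or
  Kruskal–Wallis + Dunn; Dunn's rank z-statistics use the tie-corrected
  formula with Bonferroni over the 21 pairs.  The reported "minimal
  equivalent days" is the smallest d whose adjusted p against the 7-day
  baseline exceeds 0.05.

## What the synthetic experiments show — and don't

Passing tests establish that the pipeline detects the planted group structure
(episodic high-amplitude tremor plus reduced movement amplitude under heavy
lifestyle nuisance), that it finds *nothing* on null cohorts, that combining
windowing strategies and reducing by GA improves on every single-strategy
set, that more days of data help until a plateau, and that every numerical
component matches an independent oracle.

One directional property of the original real-data analysis does **not**
reproduce on this generator, and the test suite reports it as a failure
rather than hiding it: term-frequency word features do not significantly
outperform averaged statistical features here.  The reason appears
structural, not a bug.  A subject's week contributes 10⁴–10⁵ windows drawn
from a stationary bout-mixture process, so the 50 descriptor means are
estimated essentially without noise and — for any smooth family of window
distributions — form a near-sufficient summary that a multivariate
classifier can exploit, including cancelling nuisance across channels.
Quantized term frequencies pay a binning cost against that baseline.  The
advantage of word features reported for real cohorts plausibly rests on
nonstationary, richly multimodal behavior that this deliberately parsimonious
generator does not emulate; engineering a generator specifically so that
words win (e.g. moment-matched mixture constructions) would say nothing
about the method.  Treat the word-vs-statistics comparison on synthetic data
as an honest negative with an identified mechanism.

None of this establishes clinical validity: the generator's bouts, activity
types and tremor are far simpler than human behavior (no gait harmonics, no
postural transitions, no medication cycles, no missing data), its "days" are
compressed, and its effect sizes are chosen, not measured.  Accuracy values
on synthetic cohorts are properties of the chosen effect sizes, never
estimates of clinical performance.

## Problem sizes used by tests and the acceptance script

Heavy checks run at: null calibration — 5 cohorts of 60 subjects, 2 day
units, 100 CV runs each; signal recovery — one desk cohort at the full 7
compressed day units, 100 CV runs; directional replication — 20 cohorts of
30 subjects, 2×900-s day units, 8 CV runs × 3 classifiers per feature set;
day-amount analysis — 60 subjects, 7×600-s day units, 50 CV runs per day
count; determinism — two identical reduced-size end-to-end runs.  The
acceptance script uses 60-subject cohorts with 3 day units (feature/windowing
workflow, 15 CV runs) and 7×600-s day units (day-amount workflow, 50 runs).
These sizes trade Monte-Carlo precision against runtime and keep the whole
suite in the tens of minutes on one core.
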