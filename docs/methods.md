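# Methods

## Overview

`eegtda` implements an EEG biomarker pipeline for discriminating mild
cognitive impairment (MCI) from healthy cognitive aging and regressing
Montreal Cognitive Assessment (MoCA) scores. The chain is: multichannel
oddball EEG → band-pass and empirical-mode-decomposition (EMD)
preprocessing → per-epoch topological features of the embedded point
cloud → rank-sum group statistics, unsupervised 2-D projections, and
leave-one-subject-out (LOSO) random-forest classification/regression.
Because clinical EEG of this kind cannot be redistributed, the package
ships a synthetic study generator whose statistical structure matches
what the analysis assumes, so every stage is exercised end to end
without any external data.

## Synthetic studies

A study is a cohort of subjects, each with a continuous 8-channel
recording at 250 Hz and an event table. The oddball design is 8
sessions × (1 cue display + 8 stream images) = 72 stimulus displays per
subject; each session's stream contains the target image once and seven
distractors, with four reminiscent and four contemporary image
identities. Cue displays are counted with targets by default
(16 TGT / 56 IGN per subject), controlled by
`StudyConfig.cue_counts_as_target`.

Signal model (deliberately simple, with no claim of physiological
realism): per-channel pink (1/f) noise of 5 µV standard deviation plus
a stimulus-locked damped 10 Hz burst (25 µV, decay constant 1 s) whose
per-channel phases follow a fixed gradient across the 8 channels. A
coherent phase-gradient burst makes the 8-dimensional trajectory of the
epoch trace a large clean loop, which is exactly the structure the
dimension-1 persistence features detect. Subject severity s ∈ [0, 1]
and the study-level `effect_size` e jointly degrade the burst: both its
amplitude and its cross-channel phase coherence scale with 1 − s·e
(phase jitter grows to π at full degradation). At e = 0 the two cohorts
are statistically exchangeable, which is the null used for calibration
checks; at e = 1 healthy subjects (s ≤ 0.25) have strong coherent loops
and impaired subjects (s ≥ 0.35) progressively lose them.

MoCA scores are integers in [0, 30] drawn as round(30 − 12 s + N(0, 1)),
clipped to ≥ 26 for healthy and ≤ 25 for impaired subjects (the standard
MoCA screening cutoff, adopted as a generator convention); the link is
monotone decreasing in severity, which is what makes MoCA regression
recoverable. Ages are N(70.70, 5.32) years clipped to [60, 90] and are
cosmetic. Eye-blink artifacts are smooth ~0.4 s monophasic transients
with a frontal-dominant topography at Poisson-random onsets.

Everything is a pure function of the configuration: per-subject RNG
streams are spawned from `master_seed` via `numpy.random.SeedSequence`,
so the same config reproduces a study bitwise.

What the generator does *not* emulate: realistic ERP morphology (P300),
1/f slope variation, channel-specific spectra, volume conduction, and
non-stationary artifacts. Passing tests therefore demonstrate that the
pipeline recovers the kind of group structure it assumes, not that it
would perform identically on clinical EEG.

## Preprocessing

Fixed order: filter → epoch → clean.

* **Band-pass** 1–40 Hz, zero-phase (forward–backward) 4th-order
  Butterworth via `scipy.signal.sosfiltfilt`. Zero-phase filtering
  preserves stimulus-locked latencies; the effective attenuation is
  doubled by the two passes.
* **Epoching**: half-open windows [onset, onset + 2 s) — 500 samples at
  250 Hz — one per stimulus event; events whose window overruns the
  recording are dropped and logged. No baseline correction and no
  re-referencing.
* **EMD cleaning**, per channel per epoch: the signal is sifted into
  intrinsic mode functions (IMFs) with cubic-spline envelopes through
  the local extrema (two extrema mirrored at each boundary); every
  component — IMFs and the residual trend alike — whose peak absolute
  amplitude strictly exceeds 100 µV is discarded and the survivors are
  summed. Components exactly at 100 µV are kept.

Sifting parameters: Cauchy criterion Σ(h_prev − h)² / Σ h_prev² < 0.05,
at most 10 sifting iterations per mode and 10 modes. Two additional
stopping refinements proved necessary and are package design choices:

1. The Cauchy stop is only honoured once the candidate also satisfies
   the IMF condition (extrema and zero-crossing counts differ by ≤ 1).
   The energy criterion alone can quit one iteration before a large
   transient has fully left the mode, leaving tens of µV of blink in
   the "oscillatory" component.
2. A further mode is extracted only while the residual has at least two
   maxima and two minima with prominence ≥ 2% of its range. Extrema
   below that prominence are interpolation noise riding a trend;
   sifting them amplifies cubic-spline overshoot into spurious
   large-amplitude modes (observed ~80 µV from ~2 µV of numerical
   junk next to a 300 µV transient).

A note on separability: a transient blink superposed on a low-amplitude
oscillation is cleanly separated (a 300 µV smooth transient one 1.5 Hz
period wide over a 10 µV 12 Hz tone is removed with the retained signal
correlating > 0.99 with the tone). A *sustained* large slow sinusoid
mixed with a weak fast tone is not separable by any extrema-based EMD:
when the slow component dominates the derivative, the mixture has only
the slow extrema and itself satisfies the IMF condition, so sifting
correctly treats it as a single mode. This is a property of EMD, not of
this implementation.

## Topological features

Each cleaned epoch (8 × 500) is read as 500 points in R⁸ (sample i ↦
the 8-vector of channel values). No delay embedding, no normalisation
by default (a z-score flag exists for sensitivity analyses). The
Vietoris–Rips filtration over Euclidean distances with Z/2 coefficients
yields dimension-0/1 persistence diagrams.

The production engine uses persistent cohomology with clearing:
dimension 0 by union-find over the sorted edge list; dimension 1 by
reducing the coboundary columns of the cycle-creating edges in reverse
filtration order with lazily enumerated triangle cofacets, so the
dominant zero/short-persistence pairs never materialise a full column.
The filtration is capped at the enclosing radius (min over points of
its max distance to the rest); at that scale the complex is a cone, so
the dimension-0/1 diagrams are provably identical to the uncapped ones
and every 1-cycle has a finite death. Ties in diameter are broken by a
fixed combinatorial order; the diagram does not depend on the
tie-break. The engine is verified to agree exactly (≤ 1e−9) with an
independent brute-force boundary-matrix reduction on hundreds of random
small clouds.

Six per-epoch features from the dimension-1 diagram (lifetimes
ℓᵢ = dᵢ − bᵢ, L = Σℓᵢ):

| feature | definition |
|---|---|
| total_cycles | number of dimension-1 intervals |
| max_cycles | peak of the Betti-1 curve (most simultaneously alive cycles) |
| max_persistence | max ℓᵢ |
| npe | −Σ (ℓᵢ/L) log(ℓᵢ/L) / log(total_cycles); 0 when ≤ 1 cycle |
| max_persistence_ratio | max dᵢ/bᵢ |
| median_persistence_ratio | median dᵢ/bᵢ |

The per-cycle ratio is death/birth: the only dimensionless per-interval
ratio that is scale-invariant, which is what a "ratio" feature should
be; the choice is isolated in one function (`persistence_ratio`) so
alternatives (lifetime/birth, lifetime/total) can be swapped. With no
cycles all six features are 0. Counts, entropy and both ratios are
invariant under global scaling of the cloud; max_persistence scales
linearly.

## Group statistics

For each feature × condition (TGT, IGN, ALL) the healthy vs impaired
epoch-level distributions are compared with a two-sided Wilcoxon
rank-sum test: U from midranks, p from the normal approximation with
tie and continuity corrections. The common-language effect size
P(X > Y) + ½P(X = Y) is computed by exhaustive pair counting, and the
single-feature ROC AUC from midranks; CLES ≡ AUC ≡ U/(n₁n₂) is an
identity, implemented by three routes and asserted to 1e−12.
Shapiro–Wilk normality p-values are reported per group on at most 500
values (the test's reliable range). Tests run at epoch level to mirror
the per-epoch feature distributions; **epochs within a subject are not
independent**, so these p-values are descriptive — a subject-level
aggregation (median per subject) is available. No multiple-testing
correction is applied across the 18 panels; raw p-values are reported.

## Projection and evaluation

UMAP (n_neighbors 15, min_dist 0.1) and t-SNE (perplexity 30, lowered
for small inputs) embed the six z-scored feature columns in 2-D,
deterministically given a seed. The projector receives only the feature
columns — never labels — which the test suite enforces by checking that
scrambling labels cannot move a single point. Features are standardised
before projection because counts and entropies live on incommensurate
scales.

Evaluation is leave-one-subject-out: one fold per subject, test = all
of that subject's epochs, train = everyone else's. Classification uses
a 200-tree random forest (other settings at library defaults, seeded;
the goal is feasibility, not classifier tuning) with MCI as the
positive class; headline f1/precision/recall are weighted across
classes (well-defined under imbalance), per-class values are carried
alongside. Panels aggregate per-fold metrics as median and 2.5–97.5
percentile interval, plus pooled values over all held-out epochs. AUC
is pooled (a single held-out subject has one class, so per-fold AUC is
degenerate and reported as NaN with a warning). Regression r², MSE,
MAE, MAPE are pooled for the same reason; per-fold median_error is
|median prediction − true MoCA| per subject. The chance level of an
unbalanced cohort is the majority-class proportion as an integer
percent (16 of 23 → 70%).

## Problem sizes

Feature extraction dominates runtime (≈ 0.5–1 s per 500-point cloud),
so the packaged checks use deliberately compact studies, chosen as the
package's own working sizes: the full-effect recovery study uses 23
subjects (10 healthy / 13 MCI) × 2 sessions = 18 epochs each at full
2-s epochs; the 100-seed null calibrations (type-I error of the
18-panel comparison, LOSO accuracy at zero effect) use 4–6-subject
cohorts with 0.5-s epochs. Exchangeability under the null and the
direction of the effect are unaffected by epoch length or session
count.

### A note on null-study baselines

On label-free (null) studies, pooled epoch-level LOSO accuracy does
*not* equal the majority-class rate: it is systematically several
points below it (≈ −8 points at the cohort sizes used here).
Leave-one-subject-out removes the held-out subject from training, which
shifts the training class prior against that subject's class; with
uninformative features the forest's votes track the training prior, so
every fold is biased against its own truth. This pessimistic LOSO bias
is a property of the resampling scheme under class imbalance, worth
keeping in mind when comparing reported accuracies against a
majority-class chance level.

## Known limitations

* The persistence engine computes dimensions 0 and 1 only ("voids" are
  out of scope; no dimension-2 feature is used downstream).
* EMD is the basic single-channel variant: no ensemble averaging, no
  multivariate coupling across channels. The 100 µV rule is per
  component: a blink whose energy splits into sub-threshold modes in a
  busy mixture is only attenuated, not eliminated.
* Epoch-level statistics and evaluation treat within-subject epochs as
  exchangeable units; subject-level aggregation is available but the
  headline numbers are epoch-level by design.
* The synthetic signal model is a caricature: conclusions about
  clinical EEG require clinical EEG.
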