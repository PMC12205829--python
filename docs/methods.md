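# Methods

This note documents the models, the synthetic-data generator, the numerical
choices, and the limitations of the `selfrag` pipeline.

## Data model

A study bundles five long-format CSV tables (ratings, questionnaires,
memory responses, SCR traces, SCR events). Ratings are integers 1–9;
response timeouts are empty cells, never sentinel values, and a missing
rating implies a missing reaction time. Friend-task ratings carry no
condition (that task precedes the conditions); each self-rated trait
belongs to exactly one condition, at most 30 per condition. Questionnaire
ratings are integers −3..+3 over statements I1–I3 (illusion), C1–C4
(control), and L1 (self-location). SCR traces are 100 Hz in microsiemens
with three threat events per condition, repetition indices 1–12 unique per
participant. Validation enforces all of these invariants on read and write.

## Trait-baseline residualization

Likable traits draw systematically higher ratings than unlikable ones, and
each condition holds a different random 30-trait subset, so raw ratings
would confound trait identity with condition. The pipeline therefore fits
one random-intercept model, `rating ~ 1 + (1|trait)`, pooled over both
targets (self and friend) and all conditions, and carries forward the
residual `rating − grand mean − BLUP(trait)`. Grouping is by trait only; no
participant random effect is included, so the residual retains
person-specific evaluation.

The mixed-model engine is a one-dimensional profile likelihood over the
variance ratio λ = σ²_between/σ²_within. For a single random-intercept
factor, every REML quantity reduces to per-group sums via the Woodbury
identity, so each profile evaluation is O(N). λ is located on a coarse
log-grid (0 and 97 points over 10⁻⁸..10⁸) and refined by bounded Brent
search in the bracketing interval (tolerance ≤ 10⁻⁸ on the ratio); REML
rather than ML is used throughout so variance components are unbiased by
the fixed effects. BLUPs use the standard shrinkage
λn_g/(1 + λn_g) toward the GLS fixed-effect fit. A residual variance that
collapses numerically to zero (constant input, noiseless constructions) is
flagged with a warning rather than an error. The same engine, with
arbitrary fixed-effect design matrices, backs the SCR habituation model and
the questionnaire mixed model; tests verify it against a dense-matrix
grid-search oracle (10⁻⁴ on both variance components) and against
statsmodels MixedLM.

Timeout rows carry no residual and are silently excluded from clustering;
their count is recorded on the residual table.

## Fragmentation statistics

Within each participant × condition cell, residualized ratings give 1-D
Euclidean distances `|r_i − r_j|`. Average linkage (UPGMA) merges the
closest pair of clusters repeatedly, with inter-cluster distance the
unweighted mean over all cross-pair leaf distances (Lance–Williams update);
ties in the minimum break toward the lowest cluster-index pair in creation
order, which makes merge order deterministic and label-stable. UPGMA is
reducible, so merge heights are non-decreasing; the implementation asserts
this on every run.

The **fragmentation index** is the mean of the merge heights — read
directly off the linkage output as "the mean distance between all detected
clusters". Other readings exist (e.g., averaging only heights above a
floor); the all-heights reading follows the linkage function's own output
convention and is the documented choice. The **cluster-count proportion**
cuts the dendrogram at each cutoff in 0.1..1.5 (step 0.1, distance
criterion, not inconsistency), averages the cluster counts over the grid,
and divides by the number of rated leaves, correcting for cells with
different numbers of rated traits. Cutoffs are applied to raw residual
distances without per-participant rescaling; note the scales differ —
residual distances can exceed 1.5, and no optimal-cutoff selection is
attempted. As a semantic control the same machinery re-clusters *friend*
ratings restricted to the trait subsets later assigned to each condition;
the trait→condition assignment is taken from the full design (including
self-task timeouts) when available. Cells with fewer than two rated traits
are excluded with a warning.

## Memory scoring

Equal-variance signal detection: d′ = Φ⁻¹(H) − Φ⁻¹(F). Hits and misses come
from old items rated with a button press at encoding and belonging to the
scored condition; false alarms and correct rejections come from all of a
participant's new items, which carry no condition and are therefore shared
across that participant's four scores (forced by design — foils cannot be
split by condition). Timeouts are excluded from numerator and denominator
(a config switch can count them as "new"; off by default). Extreme rates 0
and 1 are replaced by 1/(2N) and 1 − 1/(2N) for that rate's trial count —
standard practice, logged whenever applied. Per-condition d′ values are
mean-centered within participant to remove overall capacity differences;
bias measures (c, β) are out of scope.

## Skin conductance

Amplitude is max − min over the closed window [onset, onset + 6 s] at
100 Hz (the sample at exactly +6.00 s is included), square-root-transformed
for variance stabilization. The event marker itself anchors both amplitudes
and descriptive epochs; no manual response-onset picking is performed, as
that is not reproducible from data files. Epochs span −10..+20 s
(3001 samples), are linearly detrended by least squares over the whole
epoch, then baseline-corrected by subtracting the −5..0 s mean; they are
for descriptive averaging only. Habituation is modeled as
`sqrt_amp ~ 1 + condition + (1/repetition) + (1|participant)` with
treatment coding against syncSelf. The comparison between 1/n and linear
repetition codings is reported as 2×(ML log-likelihood difference); the two
codings are non-nested with equal parameter counts, so this is a
model-fit descriptive, not a χ² test. The per-participant
ownership-reduction index regresses sqrt amplitudes on 1/repetition alone
(pooled OLS) and takes mean residual in syncSelf minus asyncSelf.

## Inference

* Paired t tests are two-sided; zero-variance differences are an error.
* The 2×2 within-subject ANOVA computes each F (df 1, n−1) as the squared
  paired t of its contrast — exact in the balanced design and verified
  against a full sums-of-squares decomposition to 10⁻¹⁰.
* Wilcoxon signed-rank drops zero differences and uses mid-ranks; for
  n ≤ 25 the null distribution of the rank sum is computed exactly by
  dynamic programming over the realized (doubled) mid-ranks, above that a
  normal approximation with tie correction.
* Spearman ρ is Pearson on mid-ranks with the t approximation
  t = ρ√((n−2)/(1−ρ²)); the memory × fragmentation correlation is
  one-sided by design and flagged as such in the report.
* The JZS Bayes factor for paired designs integrates the non-central-t
  likelihood against a Cauchy(0, r = √2/2) prior on the standardized
  effect, via the substitution δ = r·tan(θ) onto a finite interval and
  adaptive quadrature (absolute tolerance 10⁻⁸) — reproducible to two
  printed decimals and checked against a 10⁶-point trapezoid oracle at
  10⁻⁵ relative. The correlation Bayes factor applies a Jeffreys-type
  marginal likelihood with a uniform prior to the rank correlation treated
  as Pearson; it is explicitly labeled approximate and used only
  descriptively.
* Mediation fits OLS paths a (m~x), b and c′ (y~x+m), c (y~x); the
  indirect effect is a·b with a deterministic Sobel z (the percentile
  bootstrap CI, seeded and vectorized over resamples, is reported
  alongside, since bootstrap z constructions vary between toolboxes).
  c = c′ + a·b holds to machine precision.
* No multiple-comparison correction is applied anywhere.
* In the memory × fragmentation correlation and the mediation model, the
  asyncSelf fragmentation index is z-scored per participant against that
  participant's four condition values ("within" mode); z-scoring across
  participants is available as a config switch.

Exclusions are an explicit list in the analysis config (the original study
analyzed 65 of 66 participants); nothing is inferred from the data.

## Synthetic-data generator

The generator emulates the study conditions: 33 dyads, 120 traits split 30
per condition uniformly at random per participant, four latent semantic
clusters (trait i belongs to cluster i mod 4).

* **Ratings.** Trait baseline b_t ~ N(0, 1) on top of scale midpoint 5;
  per-participant cluster centers are an equally spaced zero-mean grid with
  step 1.5 (the between-cluster spread), randomly permuted over cluster
  labels, and inflated by (1 + δ), δ = 0.25 by default, in asyncSelf;
  within-cluster noise SD 0.6; observation noise SD 0.5; ratings are
  round-and-clipped to 1–9 (the discretization keeps ≥ 5 distinct values
  per condition cell ≥ 99% of the time, checked in tests). Trials time out
  with probability 0.03 in each rating task; reaction times are lognormal
  (μ = 0.7, σ = 0.4 on the log scale, median ≈ 2 s) capped at the 6 s
  response deadline. Friend ratings use an independent center permutation
  and δ = 0.
* **Memory.** Equal-variance SDT with a single criterion at d′_base/2:
  old-item evidence N(d′_c, 1) with d′_c = 1.8, minus 0.3 in asyncSelf;
  new-item evidence N(0, 1); this makes the measured per-condition d′
  unbiased for the planted values. Memory responses time out with
  probability 0.02.
* **Questionnaires.** I1–I3 means +2 in synchronous and −0.5 in
  asynchronous conditions, C1–C4 mean −2, L1 mean 0, all with unit normal
  noise round-and-clipped to −3..+3.
* **SCR.** 60 s traces per condition at 100 Hz, tonic baseline 8 µS,
  threats at 12/24/36 s (enough to cover every amplitude and epoch window;
  longer traces carry no information for any implemented statistic).
  The threat response rises monotonically from 0 to its amplitude over 6 s
  along u + sin(2πu)/(2π) — steep at both ends so that measurement noise
  inflates max − min only minimally — and recovers over a 2 s cosine ramp
  that ends before any neighboring analysis window. Amplitude is
  2.0/repetition µS (1/n habituation), attenuated by 0.4 in asyncSelf;
  trace noise SD 0.05 µS. Condition order is randomized per participant and
  determines the repetition indices (3 per condition, 1–12 overall).
* **Streams.** One RNG stream per participant and component, derived from
  the master seed, so adding participants or generating a component subset
  never perturbs other draws; timeout indicators live in the shared design
  stream so the ratings and memory tables stay mutually consistent.

What the generator does *not* emulate: semantic content of specific
adjectives, dyad-level correlation between the two friends' ratings,
participant-level coupling between ownership, memory, and fragmentation
(so correlation and mediation effects are null by construction), tonic SCR
drift and motion artifacts, and ordinal response styles (the latent scale
is Gaussian). Passing recovery tests therefore shows that the pipeline
measures what was planted at realistic sizes and noise levels — not that
the paradigm's empirical effects are real.

## Problem sizes in the test suite

Monte-Carlo checks run at the emulated study size (33 dyads): 200 replicate
studies for the null calibration of the fragmentation contrast (type-I
error within the binomial 95% band around 0.05, p-values uniform by KS),
100 replicates at δ = 0.25 (sign recovery and a frozen power regression
value), 100 replicates for the SCR attenuation sign, and 500 replicates for
the null coverage of the mediation bootstrap (1000 resamples each). The
example analysis drivers run a 25+25 replicate digest.

## Known limitations

* The measured trait-baseline variance underestimates the planted variance
  because round-and-clip discretization compresses extreme latent values;
  recovery tests therefore check correlation with the planted baselines
  (> 0.9), not their scale.
* The cluster-count cutoff grid (0.1..1.5) is on the scale of the original
  analysis; residual distances can exceed it, in which case the proportion
  saturates toward 1. The grid is configurable.
* The correlation Bayes factor is an approximation with no claim to match
  any specific toolbox.
* The exact-construction claim "adding a constant to one participant's
  syncSelf responses moves their SCR reduction index by exactly that
  constant" holds only at a fixed habituation fit; with the pooled fit
  refitted, a small share is absorbed by the slope. The index follows the
  operational definition (refit), and tests allow for the fit shift.
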