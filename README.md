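# selfrag

Analysis pipeline for studies that ask what happens to the *structure* of a
person's self-concept when their sense of body ownership is experimentally
reduced. In the paradigm this package targets, participants (66, in 33
friend dyads) undergo a full-body illusion: synchronous visuotactile
stimulation preserves the normal sense of owning one's body, a 3-second
visuotactile delay reduces it. Crossing synchrony with the body in view
(own vs. friend's) gives four conditions — syncSelf, asyncSelf, syncFriend,
asyncFriend. Inside each condition participants rate how well 30 trait
adjectives (of 120 total, randomly assigned) describe themselves on a 1–9
scale; ownership is indexed by illusion questionnaires and by
skin-conductance responses (SCR) to knife threats, and incidental
recognition memory for the adjectives is tested afterwards.

## The statistic at the core

For each participant and condition, ratings are first residualized against
a trait-baseline random-intercept model fitted by REML over all ratings
pooled (`rating ~ 1 + (1|trait)`), because some traits are rated
systematically higher than others. The residuals `r_i` define 1-D Euclidean
distances `d(i,j) = |r_i − r_j|`, which feed average-linkage (UPGMA)
agglomerative clustering. With `n` rated traits the dendrogram has `n − 1`
merge heights, and the **fragmentation index** is their mean — the mean
distance between all detected clusters. A complementary statistic cuts the
dendrogram at heights 0.1, 0.2, …, 1.5 and reports the mean cluster count
divided by `n`. Around this core the pipeline runs:

* a 2×2 within-subject ANOVA (synchrony × person) and paired-t contrasts
  of the fragmentation index, with JZS Bayes factors
  (Cauchy prior scale 0.7071) quantifying evidence for null effects;
* a semantic control re-clustering *friend* ratings of the trait subsets
  later assigned to each condition, plus rating-variance and reaction-time
  controls;
* signal-detection scoring of recognition memory (d′ with 1/(2N)
  extreme-rate correction, per-participant mean-centering);
* SCR amplitude extraction (max − min over 0–6 s post-threat,
  square-root transform) and a habituation model
  `sqrt_amp ~ 1 + condition + 1/repetition + (1|participant)`;
* Spearman correlations between ownership indices, memory, and
  fragmentation, and a single-mediator bootstrap mediation model.

A seeded synthetic-study generator (`selfrag.synthio`) emulates all of this
structure with planted, configurable effect sizes, so every stage is
testable end to end without any experimental data.

## Worked example

The numbered scripts under `analysis/` run the whole story on a synthetic
study (seed 7, default planted effects):

```bash
python analysis/01_simulate.py       # writes scratch/study/
python analysis/02_fragmentation.py
python analysis/04_inference.py
```

prints, among other things:

```
mean cluster distance by condition (self-ratings):
asyncFriend    0.5087
asyncSelf      0.5661
syncFriend     0.4987
syncSelf       0.4930

2x2 ANOVA interaction: F(1,65) = 24.81, p = 0.000
cluster distance asyncSelf - syncSelf: t(65) = 8.10, p = 0.000, BF01 = 0.00
friend control asyncSelf - syncSelf: t(65) = 0.93, p = 0.354
mediation indirect = -0.0008, Sobel z = -0.20, p = 0.839
```

Read: the planted asyncSelf dispersion multiplier (1 + δ, δ = 0.25) inflates
the mean cluster distance only where it was planted (self-ratings in
asyncSelf, 0.566 vs. ≈ 0.50 elsewhere); the interaction and contrast pick it
up, the friend-rating control is flat by construction, and the mediation
chain is null because the generator plants no participant-level coupling
between ownership, memory, and fragmentation. The same pipeline is available
as a CLI (`selfrag simulate | fragment | memory | scr | analyze | report`).

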