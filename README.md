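# physiosync

Analysis pipeline for **interpersonal physiological concordance** in a
two-group music-learning experiment, together with a synthetic study
generator with known ground truth. The scientific question: does acquiring
*analytical* musical knowledge (about the music itself and its emotional
expression), compared with *historical* knowledge (about its background),
align learners' autonomic arousal — and does that alignment carry the
group's effect on how much listeners come to like the music?

The package is aimed at researchers working with skin-conductance (EDA) and
heart-period recordings from groups of participants who experienced the same
stimulus, and at anyone who wants a tested, reproducible implementation of
the Marci-style concordance index and its surrogate test.

## The statistic

For each participant the preprocessed signal is reduced to slopes of a
moving 5-s window advanced in 1-s steps. For every pair of participants,
zero-lag Pearson correlations `r` are computed over running windows of 15
slopes, and the pair's **concordance index** is

```
I = ln( Σ r⁺ / Σ |r⁻| )
```

the log ratio of summed positive to summed absolute negative correlations
(a symmetric ε = 10⁻⁶ regularizes both sums). A participant's similarity
(PSC for skin conductance, PSR for heart period) is the mean of `I` over all
within-group pairs containing them, and the group-level claim is a
one-sample t of those values against zero. Significance is assessed by an
**epoch-shuffling surrogate test**: each participant's signal is cut into
1-s epochs, shuffled independently per participant, the whole chain is
re-run per permutation, and

```
p = erfc( (|s − μ₀| / σ₀) / √2 )
```

where `s` is the observed t and `μ₀, σ₀` describe the null t distribution.

Downstream, behavioral scoring (real-time pleasure presses: level 4 counts
1, level 5 counts 2; 10-item knowledge tests), JZS Bayes factors under a
Cauchy(0, 0.707) effect-size prior, cosine similarity of binary test-response
vectors, comparison of overlapping dependent correlations (Hittner z), and a
percentile-bootstrap mediation model

```
Y = cX + e      M = aX + e      Y = c′X + bM + e′
```

with indirect effect `a·b` link physiological alignment to liking change.

## Worked example

The numbered scripts under `analysis/` run the whole study on a generated
dataset (defaults: 24 participants per group, 600-s recordings at 250 Hz,
shared-event coupling 0.7 vs 0.2, full-mediation truth a=0.6, b=0.5, c′=0):

```
python analysis/01_simulate.py --seed 0
python analysis/02_preprocess.py
python analysis/03_similarity.py
python analysis/04_permutation.py --n-perm 1000 --seed 0
python analysis/05_behavior.py
python analysis/06_inference.py --seed 0
```

which prints (seed 0):

```
SC analytical : similarity +1.808 +- 0.355, t(23) = 24.96, p = 3.7e-18, d = 5.10
SC historical : similarity +0.327 +- 0.116, t(23) = 13.76, p = 1.4e-12, d = 2.81
SC group contrast: t(46) = 19.43, p = 8.3e-24, d = 5.61
HR group contrast: t(46) = 0.10, p = 0.92, d = 0.03
SC analytical : observed t = 24.96, null = 0.02 +- 1.56, p = 1.22e-57
analytical : r(22) = 0.53, p = 0.007, BF10 = 7.52
historical : r(22) = 0.20, p = 0.341, BF10 = 0.39
PSC beyond group: beta = 1.33, dR2 = 19.1%, F(1,45) = 10.96, p = 0.002
mediation: a = 1.86, b = 1.46, c = 0.34, c' = -2.38, indirect = 2.72 [1.58, 4.50]
```

Reading this: the high-coupling (analytical) group is strongly concordant
and the surrogate test confirms the similarity is temporally specific; heart
period is equally concordant in both groups, so the group effect is specific
to skin conductance; within the analytical group, more-concordant
participants increased their liking more (r = 0.53), and concordance
predicts liking change beyond group membership. In the mediation on the
*measured* concordance the group gap in PSC is so large (a ≈ 1.9 SD) that X
and M are nearly collinear — the c′/b split is then unstable (a suppression
pattern), while the total effect `c` and the sum `c′ + a·b` remain
consistent. Recovery of the *generating* paths is done against the
dataset's structural mediator (see `docs/methods.md`), where the indirect
effect comes back at its true value 0.30 on average.

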