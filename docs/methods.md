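# Methods

## The problem

Radiologists grade thyroid nodules on ultrasound with a TIRADS-style
lexicon (composition, echogenicity, margin, shape, echogenic foci,
colour-Doppler vascularity, halo, posterior features, echo texture)
and a CNN-based CADx system independently emits a malignancy score per
nodule from the images.  This package treats the CADx score as one
more candidate feature, reweights it together with the lexicon
features, searches for predictive *second-order* feature interactions
(co-occurrences of two levels that carry risk beyond their separate
effects), and compiles the result into a human-readable integer point
card with a 1–5 (4A/4B/4C) risk stratification.

## Model

Records are one-hot encoded: each categorical feature occupies a block
of positions, an absent descriptor encodes as a zero block, and the
CADx score is discretized into its own block (binary at 0.5 by
default; quantile bins or a raw real-valued slot are available).  For
an encoded sample `X` with active positions `i`, the gated attentional
factorization machine (GAFM) scores

    e_i    = V_i x_i                                  (embedding, dim k)
    t_ij   = e_i ⊙ e_j                                (interaction vector)
    a_ij   = softmax over active, retained pairs of
             p · relu(W_a t_ij + b_a)                 (MLP attention)
    logit  = b + ⟨W, X⟩ + Σ_{(i,j) ∈ Γ} a_ij ⟨e_i, e_j⟩
    P(malignant) = sigmoid(logit)

`Γ` is the gate set: pairs whose dataset-average attention ᾱ(i,j)
exceeds a threshold ε.  With ε = −∞ every pair is retained and the
model is a plain attentional factorization machine (AFM); with Γ empty
it collapses exactly to logistic regression on `X`.  The component sum
of the element-wise product equals the inner product ⟨e_i, e_j⟩, so a
single interaction tensor feeds both the attention network and the
logit.

Training is two-step: (1) fit the ungated model to convergence under
cross-entropy; (2) form ᾱ, apply the gate, and re-train from a fresh
initialization with the surviving pairs (all first-order terms stay).
After convergence, first-order weights `W_i` and pair coefficients
`ᾱ(i,j)·⟨V_i, V_j⟩` are ranked together; the top 15 enter the
scorecard (matching the length of a conventional Kwak-style card), and
their coefficients are softmax-normalized to weights summing to 1.

### Averaging divisor for ᾱ

The dataset-average attention divides the per-sample attention sum by
the *total* sample count N by default (`attention_average="total"`).
Dividing instead by the pair's co-active count (`"coactive"`) is
available.  The total divisor weights a pair's importance by its
co-occurrence support, which matters in practice: attention estimated
from a handful of co-active samples is noise, and without support
weighting rare pairs dominate both the gate and the ranking.

### Optimization

All gradients are derived and implemented by hand in numpy (the model
is a few thousand parameters; no GPU or autograd framework is
involved) and are verified against central finite differences in the
test suite.  The optimizer is mini-batch Adam, learning rate 1e-2,
batch 256, up to 150 epochs, stopping early when the epoch training
loss improves by less than 1e-6 for 20 consecutive epochs.

The FM objective is bilinear in the embeddings and visibly
initialization-sensitive at cohort sizes of a few thousand.  Three
measures stabilize which interactions the model amplifies:

* **Seeded restarts (default 3).**  Predictions come from the restart
  with the lowest training loss; the gate uses importance averaged
  across the step-1 restarts, and the pair-ranking coefficients are
  averaged across every converged fit of both steps (each estimates
  the same ᾱ·⟨V_i,V_j⟩ for a retained pair).  Initialization-dependent
  spurious interactions average out; consistently supported ones
  persist.  In the planted-interaction study conditions this moved
  recovery from roughly half of seeds to nearly all of them.
* **Embedding-only L2 (3e-4).**  Rare-pair embedding products are the
  main overfitting channel; the first-order weights stay unpenalized
  so the gate-empty model remains an exact maximum-likelihood
  logistic fit.
* **Slow attention (learning-rate scale 0.1).**  The per-sample
  softmax is winner-take-all: once a pair's attention reaches zero
  there is no recovery gradient.  Training the attention network an
  order of magnitude slower than the embeddings lets attention follow
  the learned interaction structure instead of collapsing early onto
  an arbitrary direction.

The embedding dimension defaults to k = 2.  A low-rank embedding is a
strong regularizer: it forces every pair coefficient through shared
per-level vectors, which is what makes a single genuine interaction
identifiable among several hundred candidate pairs at n ≈ 3000.
Larger k is a config knob for richer data.

### Gate threshold

ε defaults to mean(ᾱ) + 1 SD over all pairs (`gate_epsilon=None`);
any fixed value can be supplied.  At desk-scale n most pairwise
attention is noise, and the gate earns its keep by being strict: the
retained set typically holds a few tens of pairs, the model re-trained
on them generalizes at least as well as the ungated AFM, and the
genuinely supported interactions sit far above the threshold.

## Scorecard and risk stratification

The selected features' normalized weights are multiplied by an integer
factor and rounded.  The factor search scans 1–100 and keeps the
smallest factor whose rounded card preserves the ranking of the
training samples' summed scores (Spearman ≥ 0.995); a manual factor
override exists.  A pair entry contributes its points only when both
constituent levels are present.

Summed scores map to empirical malignancy rates MR(s) = M(s)/(M(s)+B(s)).
Scores observed in fewer than 5 samples are merged into their nearest
neighbouring score first (rates at tiny denominators are unstable).  A
greedy left-to-right scan then assigns maximal contiguous score ranges
[a_i, a_{i+1}) to the ordered categories while the cumulative rate of
the range stays inside the category's bounds.  Default bounds follow
TIRADS conventions — 2: exactly 0%, 3: <5%, 4A: 5–10%, 4B: 10–50%,
4C: 50–90%, 5: >90% — and are fully configurable; category 1 (normal
gland, no nodule) never receives a score range.  Categories may end up
empty; if some observed score fits no remaining category the rates are
too non-monotone for the bounds and the fit raises an error rather
than silently mis-binning.  The diagnosis threshold t maximizes F1 of
the rule "score > t ⇒ malignant" by exhaustive scan over observed
scores (smallest t on ties).

## Evaluation

Cross-validation uses a distribution-balanced stratified partition:
exact per-fold class quotas are fixed first (fold sizes differ by at
most one, per-fold positive counts within one sample of proportional),
then samples are assigned greedily in seeded random order to the
quota-eligible fold that least perturbs per-level frequencies relative
to the cohort.  This is a greedy interpretation of
distribution-balanced stratified cross-validation; plain stratified
folding is available as a fallback.  AUC is computed by rank
(concordance probability with tie correction).  Per-feature odds
ratios come from 2×2 presence tables with a 0.5 continuity correction
for zero cells and Woolf confidence intervals.  Per-fold AUCs of
methods sharing a partition are compared with paired two-tailed
t-tests (unpaired for cross-group comparisons); fold-level t-tests are
known to be anti-conservative, and a corrected-resampled (variance
inflation) variant is available but off by default, matching common
reporting practice.

In the CV experiment the AFM baseline is by definition the converged
ungated step-1 model, so AFM and GAFM share the step-1 fit within each
fold; GAFM continues with the gate and a fresh gated re-train.  The
"max-combination" control takes the per-sample maximum of the CADx
score and a logistic fit on the non-CADx features — the desk-scale
analogue of "return the diagnosis of higher malignancy from either
method".

## Synthetic cohorts

No clinical data ship with the package; every experiment runs on
synthetic cohorts with planted, known structure.  Each sample draws
one level per feature independently from configurable marginals, and

    logit = β0 + Σ βᵢ (planted levels) + Σ γ (planted level pairs) + u,
    label ~ Bernoulli(sigmoid(logit)),
    cadx  = sigmoid(slope · visible_logit + Normal(0, σ)),

where u ~ Normal(0, ω²) is a latent grey-scale severity term standing
for image evidence outside the lexicon, and `visible_logit` omits the
colour-Doppler features (`cadx_blind`): the simulated CADx emulates a
CNN reading B-mode images, which never sees the Doppler descriptors
that only the radiologist records.  This gives the score correlated
but complementary information — the premise that makes a human-AI
hybrid worth building.  Without some signal invisible to the features
(u) and some visible only to the features (the Doppler block), no
hybrid could beat both constituents and the whole exercise would be
vacuous.

Two shipped regimes, both planting the interaction
(vascular_localization = perinodular, vascular_morphology = untwisted)
at odds multiplier 2.35:

* **default** (`default_generator_spec`, n = 3000): intercept −0.90,
  five moderate first-order effects (0.20–0.40 log-odds), ω = 0.30,
  σ = 0.50, prevalence ≈ 0.43 (mirroring 1270/3002).  Effect variance
  is deliberately small: marginal odds ratios of a logistic model
  attenuate when independent effects are integrated out, and this
  regime keeps the observable 2×2 odds ratio of the planted pair
  within a few percent of its conditional value 2.35.  All remaining
  levels (well over ten) are pure noise.
* **hybrid** (`hybrid_generator_spec`, n = 6000): strong grey-scale
  effects (1.0–2.4), strong human-only Doppler effects, ω = 2.0,
  σ = 0.72, slope 0.6, CADx discretized into octiles.  Calibrated so
  the standalone CADx score AUC sits near 0.87; the regime for
  studying the hybrid gain (features-only ≈ 0.80, hybrid ≈ 0.88).

One regime cannot serve both purposes: pushing the CADx AUC to 0.87
requires a total logit SD near 2.8, which attenuates the planted
pair's marginal odds ratio to about 1.7.  The attenuation was
quantified numerically before the parameters were fixed, and the two
regimes were frozen then.

What the generator does **not** emulate: feature correlations between
descriptors (an optional shared-severity knob exists for stress
tests), reader variability between radiologists, missing-not-at-random
absence patterns, and site effects.  Passing tests therefore show the
machinery recovers known structure under clean conditions, not that it
would on any particular clinical cohort.

### What the gate can and cannot show

Whether gating improves held-out AUC over the ungated AFM depends on
the data regime.  With weak, mostly first-order signal the two models
differ by less than seed noise (the embedding L2 already suppresses
most interaction overfit); with a strong CADx score the ungated model
can even profit from the diffuse interaction structure that
conditioning on a noisy score induces among the features.  The gate's
benefit is demonstrated where interactions dominate: the gate-benefit
experiment in the test suite uses a cohort whose signal is carried by
two sparse planted interactions, with a nearly uninformative CADx and
every other level pure noise — there the gated re-train beats the AFM
in 8 of 10 seeds.

## Problem sizes

Experiments in the test suite and the acceptance script run at the
study conditions the generator defines: n = 3000 cohorts for training,
ranking and 5-fold CV comparisons, n = 6000 with a third held out for
the hybrid-gain study, n = 20000 for large-sample odds-ratio checks,
10 seeds per stochastic claim.  CV comparisons use a single restart
and a 100-epoch budget per fold (the comparison needs held-out AUCs,
not coefficient stability).

## Known limitations

* The attention MLP is the AFM reference design (one hidden relu
  layer, scalar projection); no dropout, no deeper variants.
* Softmax normalization of signed coefficients compresses
  benign-associated (negative) features toward small positive weights;
  the signed-share mode preserves signs but is not the default.
* The greedy category fit can fail on severely non-monotone rate
  tables by design (it raises with advice rather than forcing an
  assignment).
* Fold-level t-tests remain anti-conservative even though a corrected
  variant ships; p-values should be read as the field reads them, not
  as calibrated error rates.
* The two-step procedure re-estimates the gate from a finite sample;
  with very rare planted pairs (co-occurrence under a few percent)
  recovery degrades before the odds ratio does.
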