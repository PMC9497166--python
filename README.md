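# haibrid

Human–AI hybrid risk scorecards for thyroid-nodule ultrasound, built
around a **gated attentional factorization machine (GAFM)**.

Radiologists describe thyroid nodules with a TIRADS-style lexicon of
categorical ultrasound features; CNN-based CADx systems independently
emit a malignancy score per nodule.  This package treats the CADx
score as one more candidate feature, reweights it together with the
radiologist features, searches for predictive **second-order feature
interactions** (risk carried by the co-occurrence of two levels, e.g.
perinodular vascularity together with untwisted vessel morphology),
and compiles the selected features into an additive integer point card
with a 1–5 (4A/4B/4C) malignancy risk stratification and an F1-optimal
diagnosis threshold.  It is aimed at methods researchers in clinical
risk modelling who want an interpretable bridge between black-box CADx
scores and point-based reporting systems.

## Model

For a one-hot encoded nodule `X` with active positions `i`:

    e_i   = V_i x_i                               embedding, dim k
    a_ij  = softmax_ij( p·relu(W_a (e_i ⊙ e_j) + b_a) )   MLP attention
    logit = b + ⟨W, X⟩ + Σ_{(i,j)∈Γ} a_ij ⟨e_i, e_j⟩
    P(malignant) = σ(logit)

`Γ` is the **gate**: pairs whose dataset-average attention ᾱ(i,j)
exceeds a threshold ε.  With every pair retained the model is the
attentional factorization machine (AFM); with `Γ = ∅` it is exactly
logistic regression.  Training is two-step — fit the ungated model,
gate on ᾱ, re-train with the survivors — after which first-order
weights `W_i` and pair coefficients `ᾱ(i,j)·⟨V_i,V_j⟩` are ranked
together, the top 15 are softmax-normalized, scaled by a searched
integer factor and rounded into the scorecard.  See
[docs/methods.md](docs/methods.md) for assumptions, defaults and
limitations.

No clinical data ship with the package; a synthetic-cohort generator
with planted first-order effects, a planted pairwise interaction
(odds multiplier 2.35) and a simulated, partially-blinded CADx score
makes every stage testable end to end.

## Worked example

```bash
haibrid report --spec hybrid --seed 0 --n 6000 --out demo/
```

trains the full pipeline on the high-signal synthetic regime (n =
6000, standalone CADx AUC ≈ 0.87) and writes `scorecard.json`,
`risk_table.json`, `criteria.md`, `selected_features.json`,
`score_distribution.csv` and `manifest.json` under `demo/`.  The log
ends with

```
wrote artifacts to demo/ (threshold 8, F1 0.7640)
```

and the emitted `criteria.md` scorecard begins

```
| Feature | Weight | Points |
|---|---|---|
| cadx_diagnosis=q8 | 0.2892 | 15 |
| vascular_localization=central | 0.1063 | 6 |
| cadx_diagnosis=q7 | 0.0898 | 5 |
| echogenicity=marked-hypoechoic | 0.0535 | 3 |
...

Multiplication factor: 52 (rank fidelity 0.9957)
```

The single highest weight goes to the top octile of the CADx score —
the AI opinion is the strongest single feature, but far from
sufficient on its own — followed by the planted grey-scale and Doppler
effects; the F1-optimal diagnosis rule on the integer scores is
"score > 8 ⇒ suspicious"; and each risk category's observed
malignancy rate lies inside its TIRADS band (4A: 0.0591 within
5–10%, 4B: 0.4993 within 10–50% on this run).  On the default
(weak-signal) regime, `haibrid report --seed 0` recovers the planted
(perinodular & untwisted) interaction as a selected second-order
feature with 3 points.  (All numbers are what seed 0 prints; other
seeds vary.)

The same stages are callable as a library:

```python
from haibrid import (default_generator_spec, generate, encode,
                     TrainingConfig, two_step_train, rank_and_select)

spec = default_generator_spec(n=3000, seed=0)
table, truth = generate(spec)
data = encode(table, spec.dictionary)
result = two_step_train(data, TrainingConfig(seed=0))
selected = rank_and_select(result.params, result.importance,
                           TrainingConfig(seed=0), spec.dictionary,
                           coefficients=result.coefficients)
print(len(selected.entries))   # 15
```

Other commands: `haibrid simulate` (synthetic cohorts),
`haibrid train` (GAFM / AFM / LR modes), `haibrid cv`
(distribution-balanced k-fold comparison of gafm, afm, lr0, lr1,
max-combination and the CADx score alone), `haibrid stratify`,
`haibrid score` (apply a stored card to new cases, no retraining).

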