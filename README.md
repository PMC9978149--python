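# cdmpro

Cognitive diagnosis modelling for patient-reported outcomes: fit the
saturated **G-DINA** model to a short dichotomized scale, validate the
item-attribute **Q-matrix**, extract per-person **attribute-mastery
probabilities** (cognitive diagnostic probabilities, CDPs), and quantify the
incremental value of those probabilities — over the conventional total score
— for predicting a dichotomized clinical outcome.

The package targets the analysis situation of a multicenter breast-cancer
study: a 10-item cancer-specific resilience scale (5-point Likert,
dichotomized) with a bifactor attribute structure (Generic Elements A1,
Shift-Persist A2, General Factor A3), TNM stage as a covariate, and a
"decreased quality of life" outcome defined as a loss of at least 0.5 SD on
the FACT-B total (0-144) between baseline and follow-up.  Because no patient
data are public, a seeded synthetic-cohort generator reproduces the study's
statistical structure (four cohorts of 151/95/111/135), so the full pipeline
is testable end to end.

## The model

For item *j* requiring the reduced attribute pattern α\* (the restriction of
the K-vector α to the K\*ⱼ attributes with q-entry 1), the item response
function is the full factorial expansion

> g[P(Yᵢⱼ = 1 | α\*)] = δⱼ₀ + Σₖ δⱼₖ αₖ + Σₖ<ₖ′ δⱼₖₖ′ αₖ αₖ′ + … + δⱼ₁₂…K\* Πₖ αₖ

with g an identity, logit or log link.  The attribute distribution is either
saturated (free probabilities over the 2ᴷ latent classes) or a higher-order
two-parameter-logistic model, P(αₖ = 1 | θ) = logistic(aₖθ + dₖ) with
θ ~ N(0, 1).  Estimation is EM marginal maximum likelihood with monotonicity
constraints (mastering an extra attribute never lowers a success
probability).  From the fitted posterior the package derives guess/slip
parameters, latent-class and mastery classifications with their expected
accuracy, PVAF-based Q-matrix validation (mesa plots, cutoff 0.95),
item-level Wald tests against DINA / DINO / ACDM / LLM / RRUM, absolute fit
(M2, RMSEA, SRMSR, residual-correlation heatmap table) and relative fit
(AIC/BIC/CAIC/SABIC, LR test).

The prediction stage compares, per cohort, logistic risk models
**Model 1** = TNM + total score versus **Model 2** = TNM + the K mastery
probabilities, via paired AUC (DeLong), continuous NRI, IDI, Brier score
(×100), calibration tables, decision-curve net benefit and clinical impact
curves.

## Worked example

```python
from cdmpro import (SimulationConfig, generate_cohorts, fit_gdina,
                    attribute_mastery_probabilities, classification_accuracy)
import numpy as np, pandas as pd

cohorts = generate_cohorts(SimulationConfig(seed=1))
responses = np.vstack([c.responses for c in cohorts])
fitted = fit_gdina(responses, SimulationConfig(seed=1).qmatrix,
                   structural="higher_order", seed=1)
print(round(fitted.loglik, 1), fitted.converged)
cdp = attribute_mastery_probabilities(fitted)
test_acc, attr_acc = classification_accuracy(fitted)
print(round(test_acc, 3), np.round(attr_acc, 3))
```

prints

```
-2543.6 True
0.821 [0.947 0.929 0.875]
```

i.e. the pooled fit of 492 synthetic patients converged, the expected
probability that a person's modal latent class is correct is 0.82, and the
per-attribute mastery calls are right with probability 0.93-0.95 for the
specific factors and 0.87 for the general factor.  The same analysis from
the shell:

```bash
cdmpro run-all --seed 1 --out my_run     # all stages, one artifact each
cdmpro bookkeeping                        # enrollment/completion table
```

`my_run/prediction_metrics.csv` then holds one row per cohort with both
models' AUC and Brier plus NRI/IDI and their p-values; on the default
synthetic design Model 2 improves AUC in every cohort (e.g. 79.4→87.0% in
the worst cohort at seed 1) with NRI 54-85% and IDI 9.9-15.9%.

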