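# moepheno

Outcomes-driven deep **mixture of experts** (MoE) for joint clinical
phenotype discovery and in-hospital mortality risk estimation on tabular
patient cohorts with a two-tier feature split — *presentation* data
(available before a treatment decision) and *treatment* data (generated by
the intervention itself).

It is written for biostatisticians and clinical-ML researchers working with
observational registries (the motivating setting is acute myocardial
infarction complicated by cardiogenic shock, AMI-CS, and the choice between
mechanical circulatory support devices), where homogeneous-looking cohorts
hide subpopulations whose risk factors point in opposite directions: a
pooled risk model then both underperforms and obscures exactly the
heterogeneity that matters for treatment comparisons.

## The model

A selector network over presentation features x_p emits a softmax gate
vector g ∈ Δ^{K−1} — the soft phenotype membership — plus an optional
pre-treatment risk estimate r₀.  Each of K expert networks sees the
selector's final hidden layer concatenated with the treatment features x_t
and outputs a risk p_k.  The prediction is the weighted vote

    ŷ = Σ_k g_k p_k ,

trained with

    L = BCE(ŷ, y) + λ · mean_rows Σ_k g_k² + 0.1 · BCE(r₀, y).

The gate penalty (λ at one-hot gates, λ/K at uniform) regulates expert
utilization.  Hard phenotypes are argmax gates; because the selector sees
only pre-treatment data, phenotype assignment works prospectively.  Model
selection is two-stage over a (λ, K) grid under 5-fold cross-validation:
cluster stability first (mean pairwise adjusted Rand index across folds,
singular partitions scoring 0), then discrimination (AUROC).  Reporting
includes Brier-score decomposition (uncertainty/resolution/reliability),
per-cluster mortality with exact Clopper–Pearson 95% intervals, expert
weight shares, and ternary latent-space diagnostics with local AUROC/AUPRC
heatmaps.

Everything trains in pure NumPy (hand-written backprop + Adam); no deep
learning framework is required.  A synthetic AMI-CS-like cohort generator
with planted subgroups and an exact risk oracle makes the whole pipeline
testable without restricted registry data.

## Worked example

```python
import numpy as np
from sklearn.model_selection import train_test_split
from moepheno import (default_amics_spec, generate_cohort, MoEConfig,
                      build_moe, train_moe, predict_table, assign_clusters,
                      auroc, adjusted_rand_index, weight_contribution,
                      order_experts_by_weight)

spec = default_amics_spec()                 # 3 planted subgroups, 27 features
cohort = generate_cohort(spec, 10_000, seed=7)
idx = np.arange(cohort.n)
trv, te = train_test_split(idx, test_size=0.2, random_state=0,
                           stratify=cohort.outcome)
tr, va = train_test_split(trv, test_size=0.2, random_state=0,
                          stratify=cohort.outcome[trv])

cfg = MoEConfig(n_experts=3, size_preset="small", gating_l2=0.01,
                epochs=200, patience=20, seed=0)
model = build_moe(cfg, spec.schema)
model, _ = train_moe(model, cohort.subset(np.sort(tr)), cohort.subset(np.sort(va)))

pred = predict_table(model, cohort.subset(te))
labels, gates = assign_clusters(pred)
print("test AUROC:", round(auroc(cohort.outcome[te], pred.final_risk), 3))
print("phenotype ARI vs planted groups:",
      round(adjusted_rand_index(cohort.latent_labels[te], labels), 3))
order, _ = order_experts_by_weight(gates)
print("weight shares A,B,C:",
      [round(100 * weight_contribution(gates)[e], 1) for e in order])
```

Output:

```
test AUROC: 0.811
phenotype ARI vs planted groups: 0.725
weight shares A,B,C: [44.6, 30.9, 24.5]
```

The cohort's event rate is 0.257 and the generative (Bayes) oracle scores
AUROC ≈ 0.85 at this size, so the fitted mixture is within a few points of
the ceiling while recovering the planted phenotypes (ARI 0.73); a pooled
ridge-logistic baseline reaches only ≈ 0.69 on this cohort.  Expert A is
the heaviest phenotype (44.6% of the vote).  `cluster_outcome_rates` then
tabulates per-phenotype mortality with exact intervals, e.g. phenotype A
at `34.1 (31.1–37.1)` percent versus `15.4 (12.4–18.9)` for phenotype B.

The same stages are scriptable from a shell:

```bash
moepheno simulate --n 10000 --seed 7 --out run/
moepheno train --cohort run/cohort.csv --schema run/schema.yaml -k 3 --out run/
moepheno analyze --cohort run/cohort.csv --schema run/schema.yaml --model run/model --out run/
moepheno plot    --cohort run/cohort.csv --schema run/schema.yaml --model run/model --out run/
```

See `docs/methods.md` for the model, selection procedure, generator design
and known limitations.

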