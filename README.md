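# survclust

Survival-guided clustering for right-censored cohorts: train any neural
network to partition subjects into k prognostically distinct groups by
directly maximizing survival heterogeneity between the groups.

Clinical risk stratification usually either clusters patients on feature
similarity (with no guarantee the clusters differ in outcome) or fits
continuous risk models that never yield actionable group boundaries.
`survclust` closes that gap with a differentiable, probabilistic relaxation
of the k-sample multivariate logrank statistic: group membership indicators
become softmax probability rows, observed events and risk-set masses become
probability-weighted sums, and the statistic

    L = Zᵀ V⁻¹ Z,   Z_g = Σ_j (O_{g,j} − E_{g,j}),

with V the hypergeometric variance–covariance of the event allocation,
becomes an end-to-end differentiable training objective. Because the raw
statistic rewards degenerate, imbalanced assignments, the minimized loss
adds an asymmetric barrier on the mean assignment proportions p̄:

    loss = −L + λ P(p̄),
    P(p̄) = (1/k) Σ_g 1/(p̄_g^α − (p̄_g^α)²) − 4,   α = ln(1/2)/ln(1/k),

which is exactly zero at uniform proportions and diverges as any cluster
empties or swallows the cohort. With one-hot assignments the relaxed
statistic reproduces the classical k-sample logrank statistic to 1e-8
(tested against an independent reference over hundreds of random cohorts).

The package bundles:

* `survclust.logrank` — risk tables, the covariance matrix, the classical
  and soft statistic, the balance barrier, and the total loss;
* `survclust.autodiff` / `survclust.nn` — a compact reverse-mode autodiff
  engine over numpy and the two reference architectures (tabular MLP,
  image CNN) with AdamW;
* `survclust.simulate` — seeded tabular and glyph-image cohort generators
  with planted prognostic classes and calibrated independent censoring;
* `survclust.train` — mini-batch training and event-stratified 5-fold
  cross-validation with leakage-free preprocessing;
* `survclust.evaluation` — cluster-to-truth matching, per-class
  AUROC/AUPRC, Harrell's c-index with bootstrap confidence intervals and
  paired-difference tests, Kaplan-Meier summaries;
* a `survclust` command line (`simulate`, `train`, `evaluate`,
  `demo-tabular`, `demo-image`).

## Worked example

Train the default tabular study end to end — a 3-class synthetic cohort
(n = 1500, class hazards 2.0/0.7/0.25 per time unit, 30% censoring) and
the default MLP under 5-fold cross-validation — then score the held-out
assignments:

```python
import numpy as np
from survclust.simulate import SyntheticSpec, simulate_tabular_cohort
from survclust.train import TrainConfig, cross_validate
from survclust.evaluation import evaluate_clustering

X, cohort, labels = simulate_tabular_cohort(SyntheticSpec(seed=0))
cv = cross_validate(cohort, X, TrainConfig.for_mlp(seed=0), k=3, kind="mlp")
report = evaluate_clustering(cv.assignments, cohort, true_labels=labels,
                             n_boot=2000, seed=0)
print("matched per-class AUROC:", np.round(report.auroc_per_class, 3))
print("c-index: %.3f  95%% CI (%.3f, %.3f)"
      % (report.c_index, *report.c_index_ci))
print("logrank p across clusters: %.3g" % report.logrank_p)
for s in report.km_summaries:
    print("cluster %d  n=%d  median survival %.3f"
          % (s["cluster"], s["n"], s["median_survival"]))
```

Output (seed 0):

```
matched per-class AUROC: [0.929 0.872 0.94 ]
c-index: 0.654  95% CI (0.639, 0.670)
logrank p across clusters: 2.89e-70
cluster 0  n=644  median survival 2.042
cluster 1  n=405  median survival 0.791
cluster 2  n=451  median survival 0.424
```

Reading the numbers: the model was never shown the planted class labels —
it clustered purely by survival signal flowing through the features. The
matched AUROCs measure how well the discovered clusters recover the
planted classes (1.0 = perfect recovery, 0.5 = chance); the c-index
measures how well the cluster risk ranking orders individual survival
times (0.5 = chance); the logrank p-value describes the separation of the
three Kaplan-Meier curves, and the cluster medians show the recovered
risk gradient (cluster 0 = best survival by convention; a factor ≈ 5
between best and worst cluster median here). The same workflow runs from
the shell:

```sh
survclust demo-tabular --seed 0 --out runs/demo-tabular
survclust demo-image   --seed 0 --out runs/demo-image
```

Each run directory contains the frozen config, held-out soft assignments,
per-cluster Kaplan-Meier curves as CSV, a JSON report with the fields
printed above, and a JSON-lines training log.

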