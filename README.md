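# fedrad — privacy-preserving distributed radiomics modelling

Multicenter radiomics studies need large cohorts, but patient-level imaging
features usually cannot leave the hospital that produced them. `fedrad`
implements a complete *horizontally federated* modelling workflow for tabular
radiomic features (patients × features, one table per site) with a binary
endpoint such as tumor HPV status or 2-year overall survival: every step that
normally touches the pooled data is replaced by an exchange of
patient-count-independent aggregates between site nodes and a coordinator,
and a centralized reference implementation of each step is provided so the
two can be compared end to end.

The pipeline, in the order it runs:

1. **Quality control.** A feature is excluded when its missing fraction
   exceeds 20% or |skewness| > 5. Distributed mode applies the rules per
   cohort and excludes the union.
2. **Normalization.** Global mean and SD per feature are pooled exactly from
   site summaries — μ = Σ nₖμₖ/N and SS = Σ(SSₖ + nₖ(μₖ−μ)²) — and every
   site z-scores locally with the global statistics.
3. **Correlation pooling.** Global inter-feature correlations are estimated
   by inverse-variance-weighted averaging of Fisher-transformed local
   coefficients: z̄ = Σ(nₖ−3)·atanh(rₖ) / Σ(nₖ−3), r̂ = tanh(z̄).
4. **Feature selection.** Average-linkage hierarchical clustering on
   distance 1−|r| with a 0.6 correlation cutoff; one representative per
   cluster by univariate AUC — centrally gated by Benjamini–Hochberg
   FDR < 0.05, distributedly by cohort-size-weighted voting with an 80%
   selection-rate threshold.
5. **Classification (GLORE).** Federated logistic regression by intermediate
   aggregation of Newton–Raphson solutions: each iteration every site sends
   its gradient Xᵀ(y−p) and Hessian XᵀWX, and the coordinator updates
   β ← β + (Σ Hₖ)⁻¹ Σ gₖ. Site aggregates sum to the pooled quantities
   exactly, so GLORE converges to the same maximum-likelihood fit as the
   centralized Newton fitter.
6. **Evaluation.** Leave-one-cohort-out validation with DeLong AUC
   confidence intervals and the paired DeLong test, calibration slope on the
   logit scale (tested against 1), classification discrepancy at the two
   models' training-median thresholds, and Kaplan–Meier risk-group curves
   with a G-rho (log-rank) test and odds ratio.

A synthetic-cohort generator (`fedrad.simulate`) produces federations with
known ground truth — block-correlated feature clusters from a factor model,
a logistic outcome on designated features, exponential survival censored at
two years, MCAR missingness, lognormal-skewed columns and site mean shifts —
so every stage is testable without patient data.

## Worked example

```python
import numpy as np, pandas as pd
from fedrad import (GeneratorConfig, generate_federation,
                    fit_logistic_glore, fit_logistic_centralized)

feats = ["c01_f01", "c02_f01", "c03_f01"]
cfg = GeneratorConfig(num_sites=4, patients_per_site=[206, 441, 100, 141],
                      num_clusters=3, features_per_cluster=3,
                      within_cluster_corr=0.6,
                      true_coefficients={"c01_f01": 1.0, "c02_f01": -0.8,
                                         "c03_f01": 0.6}, seed=4)
sites = generate_federation(cfg)
glore = fit_logistic_glore(sites, feats)
x = pd.concat([s.features[feats] for s in sites], keys=[s.site_id for s in sites])
y = pd.concat([s.outcome for s in sites], keys=[s.site_id for s in sites])
central = fit_logistic_centralized(x, y)
print(np.round(glore.beta, 4), glore.iterations,
      np.abs(glore.beta - central.beta).sum())
```

prints

```
[-0.0154  1.199  -0.9653  0.4684] 6 1.4416913763379853e-16
```

— the federated fit recovers the generating coefficients (0, 1, −0.8, 0.6)
up to sampling noise, converges in 6 Newton iterations, and agrees with the
centralized fit to 10⁻¹⁶, i.e. federation costs nothing in accuracy. The
scripts in `examples/` walk through each capability the same way
(simulation, distributed QC and pooling, clustering and selection, GLORE,
the comparison statistics, and the full leave-one-cohort-out run); a thin
CLI (`fedrad simulate|run|compare`) drives the end-to-end workflow from
per-site CSV files and a YAML config.

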