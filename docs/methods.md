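# Methods

## Setting and model

The package targets horizontally partitioned data: K cohorts (hospitals)
hold the same radiomic feature columns over disjoint patients. The modelling
goal is a multivariate logistic regression P(y=1|x) = σ(β₀ + βᵀx) over a
small set of selected features, trained either centrally (rows pooled) or
federatedly (only aggregates leave a site), with the two routes compared on
held-out cohorts. Federation here is simulated in-process: site nodes are
objects behind a query interface, and every cross-boundary message
serializes to JSON whose array dimensions depend only on the feature count.
There is no networking, encryption or authentication; the message contract
is the auditable artifact.

## Federated statistics

**Moments.** Each site reports, per feature, the non-missing count n, mean
μ, sum of squared deviations SS, missing count and skewness g1 = m₃/m₂^{3/2}
(the unadjusted estimator; the bias-corrected variant is not used by
default). Pooling is exact: μ = Σnₖμₖ/N and SS = Σ(SSₖ + nₖ(μₖ−μ)²), the
standard one-pass combination identity, so the distributed z-scoring step is
numerically identical (≤1e−12 relative) to z-scoring the concatenated data.
Skewness is flagged undefined (NaN) below 3 non-missing values or for a
constant column.

**Correlations.** Pearson correlations are computed per site on
pairwise-complete observations (complete-case mode available), clipped to
|r| ≤ 1−1e−7 to avoid infinite atanh for degenerate columns, Fisher
transformed, and averaged with weights nₖ−3 — the inverse variance of the z
statistic (plain nₖ weights selectable). The pooled matrix is symmetrized
and its diagonal forced to 1. Unlike moment pooling this is approximate;
with homogeneous sites of n = 200 the elementwise error against the
pooled-data correlation stays below 0.05, which is what the clustering
consumes. Sites with n ≤ 3 carry no information on the z scale and are
excluded with a warning.

**Newton messages.** At coefficients β each site returns gradient Xᵀ(y−p),
Hessian XᵀWX (W = diag(p(1−p))) and the Bernoulli log-likelihood, computed
over complete cases (rows missing any model column or the label are dropped
and counted). These are sums over rows, hence exactly additive across any
row partition — the property the GLORE equivalence rests on.

## Quality control

Thresholds: missing fraction > 0.20 or |skewness| > 5, both strict, so
boundary values are retained. Absolute skewness is used because the rule
exists to catch outlier-driven distributions, which can be skewed in either
direction; a signed mode is available. Centralized QC evaluates both rules
on the concatenated rows; distributed QC evaluates them per cohort and
excludes the union, which makes the distributed exclusion set monotone in
the number of sites and identical to centralized QC when K = 1.

## Feature selection

Features are clustered by average-linkage agglomeration on distance
1 − |r|, cutting the dendrogram at height 1 − 0.6, so clusters keep an
average absolute correlation of at least 0.6. Absolute correlation is the
default because two strongly anti-correlated radiomic features are as
redundant as two correlated ones; a signed-distance mode exists. Cluster
labels are renumbered in order of first appearance, making them
deterministic for a fixed column order (and invariant to column permutation
up to relabelling).

The centralized route screens every retained feature with a univariate
logistic regression; the feature's AUC is max(a, 1−a) of the rank AUC (the
logistic link is monotone, so the model's AUC depends only on ranks), and
the Wald p-value of the slope feeds a Benjamini–Hochberg adjustment across
*all* retained features — not only cluster winners — because the univariate
screen is run on the whole feature set before representatives are picked.
A cluster's max-AUC feature is selected iff its adjusted p < 0.05. AUC ties
break to the smallest feature id, a platform-independent rule.

The distributed route has no FDR gate: each cohort votes for its locally
best feature per cluster, votes are weighted by cohort size, and a feature
is selected when its weighted selection rate is ≥ 80% (non-strict). With a
single cohort this reduces to per-cluster max AUC with weight 1. Raising the
threshold can only shrink the selection (monotonicity, tested).

The cluster-overlap metric between the two clusterings sums, over
centralized clusters, the size of the largest distributed subcluster and
divides by the feature count. Note the edge case: all-singleton centralized
clusters give overlap 1 regardless of the distributed labels.

## Model fitting

Both fitters run damped Newton–Raphson from β = 0 (identical initialization
keeps iteration counts comparable) with convergence when the L∞ norm of the
applied update drops below 1e−8 — comfortably inside the 1e−7 coefficient
agreement the equivalence tests assert. A step that would decrease the
pooled log-likelihood is halved up to 10 times; this never moves the fixed
point, only the path. Degeneracies: a singular Hessian raises an error
naming the collinear columns (QR diagnostic); ‖β‖∞ > 30 on standardized
inputs, or a saturated log-likelihood (ll → 0) without coefficient
convergence, raises a separation error, since no finite MLE exists. Model
features are the z-scored (global statistics) versions of the selected
features, which makes the separation bound scale-free. Complete-case
analysis throughout; no imputation.

## Evaluation statistics

The DeLong machinery is implemented from the structural components: V10ᵢ is
the mean tie-corrected placement of positive i against all negatives (V01
symmetric), AUC = mean(V10), var = S10/m + S01/n with sample (co)variances;
the paired test uses the 2×2 component covariance and a normal reference,
returning p = 1 for identical score vectors. Calibration regresses the
observed labels on logit(p̂) — the calibration-slope convention, under which
H0: slope = 1 is meaningful; a probability-scale mode exists but its null is
not standard. Classification discrepancy dichotomizes each model at the
median of its own training-cohort predictions, ties classifying high-risk.
Kaplan–Meier estimation and the G-rho (Fleming–Harrington) test are
delegated to lifelines, with ρ = 0 (the plain log-rank) by default. The
risk-group odds ratio uses the 2×2 table of group × death-within-horizon
with the Haldane–Anscombe 0.5 correction when a cell is empty and a Woolf
CI.

## Synthetic federations

The generator emulates the structure the workflow assumes. Features follow
a factor model: feature j in cluster c is √ρ_b·g + √(ρ_w−ρ_b)·u_c +
√(1−ρ_w)·ε with standard-normal global factor g, cluster factor u_c and
noise, so each feature is marginally N(0,1) and the expected correlation is
exactly ρ_w within and ρ_b between clusters. The binary endpoint is
Bernoulli with logit β₀ + βᵀx on the *pre-shift* feature values, so additive
site mean shifts (drawn once per site per feature from N(0, σ²)) are pure
measurement nuisance. Survival times are exponential with rate
λ₀·exp(βᵀx) — the covariate part only, λ₀ playing the baseline role — and
administratively censored at 2 years; any monotone-hazard family would do,
since the workflow consumes only the 2-year binary label plus (time, event)
for KM display. Missingness is MCAR with an exact per-column count;
skewed columns are exp(severity·z), lognormal-shaped, exceeding skewness 5
at severity ≥ 2 for n ≥ 100. Default cohort sizes (206, 441, 100, 141)
mirror a realistic 2–4× imbalance across hospitals.

What the generator does **not** emulate: multiplicative or
correlation-structure scanner effects, informative missingness, non-normal
marginals beyond the injected skew, and competing risks. Passing tests
therefore demonstrate algorithmic correctness and the exactness/closeness
properties of the pooling formulas — not robustness to every real-world
acquisition artifact.

## Endpoints

`binary_outcome` uses the stored label; `survival_2y` derives
death-before-2-years from (time, event). Patients censored alive before the
horizon have unknown 2-year status and are excluded from modelling, the
conservative reading when cohorts list "unknown" 2-year survival.

## Problem sizes and reproducibility

The test suite and the acceptance script run on deliberately modest
problems — federations of 3–5 sites with 100–441 patients and 6–20
features, 20–200 Monte-Carlo replicates — chosen so the full suite
completes in well under a minute while keeping every Monte-Carlo band
(correlation pooling error, DeLong type-I rate, Wald coverage) comfortably
away from its threshold at the seeds used. All randomness flows through
`numpy.random.default_rng` seeds carried in the configs; reports are
byte-identical across reruns.

## Known limitations

Fisher pooling is biased for very heterogeneous sites (large mean shifts
change local correlations); the workflow inherits the assumption that
feature distributions are similar across cohorts. The distributed selection
can legitimately return an empty set when cohorts disagree — the workflow
reports the fold without a model rather than relaxing the threshold. The
separation heuristic is a diagnostic, not a remedy; penalized fits are out
of scope, as are stepwise selection, recalibration and real network
transport.
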