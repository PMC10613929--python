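# Methods

## Problem and model

`moepheno` targets a problem common in observational outcome registries:
patients with a single admitting condition (the motivating case is acute
myocardial infarction complicated by cardiogenic shock, AMI-CS) form
heterogeneous subpopulations whose risk factors can differ in *direction*,
so a single pooled risk model both underperforms and hides the subgroups.
The package jointly learns soft patient phenotypes and in-hospital mortality
risk with a deep mixture of experts (MoE) over a two-tier feature split:

* **presentation tier** — data available before a treatment decision;
* **treatment tier** — data generated during/after intervention (device use,
  peak labs, complications), informative for risk but contaminated by the
  treatment choice and therefore excluded from phenotyping.

A *selector network* (MLP over presentation features) produces a softmax
**gate** vector g ∈ Δ^{K−1} over K experts — interpreted as soft phenotype
membership — and, in the default configuration, an auxiliary pre-treatment
risk estimate r₀.  Each *expert network* consumes the selector's final
hidden layer (pass-through) concatenated with the treatment features and
outputs a risk pₖ; the model prediction is the weighted vote
ŷ = Σₖ gₖ pₖ.  Hard phenotype labels are argmax gates (ties → lowest
index).  Because the selector sees only presentation data, the phenotype
assignment remains usable prospectively, before treatment.

The training loss is

    BCE(ŷ, y) + λ · mean_rows Σₖ gₖ² + 0.1 · BCE(r₀, y)

The L2 gate penalty equals λ at one-hot gates and λ/K at uniform gates, so
it pushes against concentration of the vote on a single expert; large λ
flattens the gates entirely.  A config flag moves the penalty to the
pre-softmax gate scores instead.

### Architecture presets

| preset | selector hidden | expert hidden |
|--------|-----------------|---------------|
| large  | 3 × 50 (ReLU)   | 3 × 50 (ReLU) |
| mid    | 2 × 24          | 2 × 24        |
| small  | 2 × 24          | none (single logistic prediction layer) |

The expert count is capped at 10: few experts keep phenotypes clinically
interpretable and avoid the shrinking-batch problem of wide mixtures.
Connection variants: `standard` passes the selector's last hidden layer to
every expert; `later_hidden` injects the selector's *first* hidden layer
immediately before each expert's prediction layer; `no_hidden` gives experts
only raw presentation + treatment features.  The two non-standard variants
are labeled approximations — the reference behavior is `standard`.

### Training and numerical choices

Everything is NumPy with hand-written backprop (finite-difference-verified
in the test suite) and Adam (lr 1e-3, batch 256), early stopping on
validation loss (patience 10 by default; the pipeline stages use 15–25) with
best-checkpoint restoration.  Hidden units are ReLU; output units logistic.
Continuous features are z-scored with moments learned on the training split;
missing values are imputed binary→0 ("no"), continuous→training-split mean.
Training is single-threaded deterministic given the config seed.

**Gate initialization.** The joint gating objective is multi-modal: cold
starts can settle where planted subgroups are split or merged across experts
with almost no predictive-likelihood cost.  By default the selector is
therefore warm-started toward a k-means partition of the (standardized)
presentation features — ten epochs of cross-entropy pretraining of the
selector+gate only — the mixture-model analogue of k-means-initialized EM.
Joint outcome-driven training then refines both the partition and the risk
model.  `gate_init="random"` disables this.

**Initial-risk head.** The selector's auxiliary risk output (weight 0.1 in
the loss) is on by default: it gives the selector a direct outcome signal,
which empirically stabilizes phenotype recovery; it also supplies the
pre-treatment risk estimate used at decision time.

## Model selection

Five-fold stratified cross-validation; each training fold donates 20% as an
inner validation split.  Per grid cell (λ, K) and fold we record test-fold
AUROC, AUPRC and the Brier decomposition, and the fold's full-cohort
phenotype partition.  Cluster stability is the mean pairwise adjusted Rand
index (ARI) over the 10 fold pairs; a partition with a single nonempty
cluster is "singular" and each pair involving one contributes 0.  Fold
partitions are compared on the full cohort by default so all pairs share an
item set (a test-folds-only mode pairs on test-set intersections).

Configuration choice is two-stage: (1) shortlist λ values whose best mean
ARI is within one CI half-width (mean ± 1.96·SE over pairs) of the global
best and pick the modal ARI-maximizing K among them (ties → smaller K);
(2) among shortlisted λ at that K, maximize mean AUROC (ties → smaller λ).
The default λ grid is {0.001, 0.002, 0.004, 0.006, 0.008, 0.01, 0.05, 0.1},
K ∈ {2..10}.  A pooled ridge-logistic baseline (penalty tuned on the inner
split) provides the homogeneous-model reference.

The Brier decomposition uses 10 equal-width probability bins:
uncertainty = ȳ(1−ȳ), resolution = Σ(n_b/n)(ȳ_b−ȳ)², reliability =
Σ(n_b/n)(p̄_b−ȳ_b)²; reliability − resolution + uncertainty equals the
Brier score exactly under bin-mean forecasts.  This is the standard
decomposition, bounded by 0.25 for each binary-outcome component.

Cluster adequacy: a phenotype is kept for reporting when its membership is
at least 10% of the largest cluster's and its share of total gate weight
exceeds 10%.

## Phenotype reports and latent space

Experts are relabeled A, B, C, … by descending total gate mass (ties keep
index order).  Reports: per-expert weight share; per-cluster feature
summaries (mean ± SD continuous, % binary, one decimal); per-cluster
mortality, overall and within treatment groups (only-IABP = balloon pump
and no other device; only-LVAD analogous; none = no device), with exact
Clopper–Pearson 95% intervals — lower = Beta(k, n−k+1) quantile at 0.025
(0 when k = 0), upper = Beta(k+1, n−k) quantile at 0.975 (1 when k = n).
A cell is flagged "non-significant" when its CI contains the population
point rate (weakest reading; an exact binomial test is the alternative
flag).

For visualization, gate mass is truncated to the three globally heaviest
experts and renormalized (truncated mass recorded per patient; a raw
non-renormalized mode is a flag).  Patients with zero mass on all three are
excluded and listed, never guessed.  Local discrimination uses a uniform
barycentric subdivision with r cells per edge (r = 10 default, r² cells):
floors of the r-scaled coordinates index the cell, fractional sums of 1/2
distinguishing upward/downward triangles and lattice points resolved by
decrementing the largest coordinate — half-open boundaries, deterministic
membership.  Cells with fewer than 10 patients or one outcome class take
fill values 0.5 (AUROC, chance) / 0 (AUPRC).

## Synthetic cohort generator

Real AMI-CS registries are access-restricted, so the package ships a
generator whose defaults define the study conditions for every test.  It
emulates the two-tier schema (12 presentation + 15 treatment features,
mirroring the published feature list) with K_true = 3 planted subgroups,
mixing (0.55, 0.30, 0.15):

* continuous features: per-group Gaussians (unit noise, standardized scale);
  binary: per-group Bernoulli;
* treatment features depend on presentation features *and* group
  (confounding by indication) through per-feature linear models — log-odds
  for indicators, conditional means for continuous;
* outcome: per-group logistic model over all 27 features.  Groups 0 and 1
  have opposite signs on age, blood pressure, troponin (initial and peak)
  and ejection fraction, so a pooled linear scorer is structurally
  handicapped; group intercepts are solved numerically at spec construction
  so group event rates hit (0.32, 0.20, 0.14), an overall prevalence of
  ≈ 0.257.
* an optional missing-completely-at-random injector (rate 0 by default)
  exercises imputation.

`bayes_risk` evaluates the generative logistic model exactly and is the
discrimination/calibration ceiling ("the oracle") in tests.  At n = 20,000
the oracle AUROC is ≈ 0.849, a pooled ridge-logistic model reaches ≈ 0.69,
and the posterior-over-groups ARI ceiling is ≈ 0.91 — room for the MoE to
demonstrate recovery (ARI ≥ 0.6, AUROC within 0.03 of the oracle) without
the task being trivial.

**What the generator does not emulate:** realistic clinical marginal
distributions or units, time-varying risk, missingness that is informative,
unmeasured confounding, and the weak/diffuse subgroup structure of real
registries.  Passing tests show the pipeline recovers *planted, strongly
identifiable* heterogeneity; they do not certify performance on real
registry data.

One documented consequence: with the gate penalty removed entirely (λ = 0),
this generator's strong planted heterogeneity keeps several experts
genuinely profitable, so the single-expert collapse reported for
under-regularized mixtures on real registry data does not reproduce here —
the dominant expert's weight share plateaus near 0.3–0.6 even after long
training without early stopping.  The corresponding test encodes the
collapse expectation and currently fails by design of honesty rather than
being weakened.

## Problem sizes used by the test suite

Recovery and expert-count-selection experiments run at n = 20,000 with
5 folds; regularization-endpoint experiments at n = 10,000 with a
convergence-scale budget (300 epochs, patience 60), since both endpoints
describe converged behavior; quick contract tests use n ≤ 5,000.

## Known limitations

* The MoE optimization remains non-convex; different seeds give partitions
  of varying quality even with the k-means warm start.  Stability across
  folds (the ARI stage) is the intended guard.
* The ternary view truncates K > 3 mixtures; the weight-contribution table
  quantifies what truncation discards.
* The auxiliary initial-risk head is trained with a fixed 0.1 weight; no
  attempt is made to tune it.
* `later_hidden` / `no_hidden` are defined here as documented
  approximations; published descriptions of these variants are not precise
  enough to guarantee equivalence.
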