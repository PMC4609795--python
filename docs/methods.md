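# Methods

## The data model

All counts are negative binomial with the mean/dispersion
parameterisation

    E[X] = μ,   Var[X] = μ + φ μ²,

φ the dispersion parameter; φ = 0 degenerates to Poisson. This is the
convention of the count-based differential-expression methods the package
re-implements, and the moment identity is what the simulator's tests pin
down (sample mean/variance within 5% of μ and μ + φμ² at 10⁵ draws).

## The simulator

A dataset is 500 features × 40 samples (20 cases, 20 controls). The first
`n_sig` features are truly differential: cases draw from
NB(μ_sig_case, φ_sig_case), controls from NB(μ_sig_control,
φ_sig_control). All remaining features are noise, NB(μ_noise, φ_noise) in
both groups. Baseline values: μ_sig_case = 20, all other means 5, all
dispersions 1, s2n = 0.1. Effects are one-directional (case means never
below control means).

The signal-to-noise ratio s2n is the ratio of significant to
insignificant features; the default convention is therefore
`n_sig = round(n_features · s2n / (1 + s2n))` (45 at baseline), with
`s2n_convention="fraction"` switching to `round(n_features · s2n)` (50).
The benchmark's sensitivity/specificity estimates are per-feature rates
and are insensitive to this choice.

The scenario grid varies one axis at a time: s2n over
{0.01, 0.05, 0.1, 0.15, 0.20} (A1–A5), the case mean of significant
features over {10, 15, 20, 25, 30} (B1–B5), and their case dispersion over
{0.125, 0.5, 1, 2, 8} (C1–C5). A3, B3 and C3 all equal the baseline.

Randomness: each replication derives its generator from
`SeedSequence((seed, rep_index))`, so replications are independently
reproducible and order-independent, which is also what makes the
replication harness deterministic under any worker count.

Significant features occupy a contiguous leading block with the truth
mask carried alongside; no shuffling is needed because every selector is
order-agnostic. The generator draws no library-size variation, batch
effects, feature correlation or zero inflation — size factors on
simulated data are therefore ≈ 1, and conclusions about selectors
transfer to real data only to the extent that these structures do not
dominate it.

## Normalisation

Median-of-ratios size factors: factor_j = median over features of
count_gj / (geometric mean of feature g), using features positive in
every sample as the reference, rescaled to geometric mean 1. Counts with
mean 5 and dispersion 1 contain many zeros, so the all-positive reference
can collapse to a handful of features; below 10 reference features the
implementation falls back to geometric means over positive entries and
medians over positive ratios (with a warning). Even then the estimator
carries sampling noise of roughly ±0.1–0.25 on such data — the tests
assert factors within 1 ± 0.3, not a tighter band, for that reason.
Normalised counts are rounded to integers before the exact test; on
simulated data this is a near no-op.

## Dispersion estimation

*Common φ (conditional ML).* For equally scaled samples, conditioning a
group's counts on their total removes the mean parameter; the per-feature
conditional log-likelihood for one group of n samples with total z and
r = 1/φ is

    Σ_j [lnΓ(y_j + r)] − n lnΓ(r) − lnΓ(z + n r) + lnΓ(n r),

summed over the two groups and over features. The maximiser over φ is
found by golden-section search on log₁₀φ ∈ [−6, 2] (relative tolerance
10⁻⁴); a maximum pinned to the lower boundary is reported as φ = 0 with a
warning, one at the cap as the cap.

*Tagwise φ (weighted conditional likelihood).* Per feature,
WL_g(φ) = l_g(φ) + α·l̄(φ), where l̄ is the across-feature mean
conditional log-likelihood. α interpolates between fully individual
(α = 0) and fully common (α → ∞) estimates. The default makes the common
component worth 20 prior observations per feature, i.e. α = 20/n_samples
(0.5 at n = 40); the constant is exposed as `alpha_weight`. For speed the
shared l̄ is tabulated on a 201-point log-φ grid and interpolated; each
feature's objective is bracketed on the grid and refined by a vectorised
golden-section search.

*Pooled mean–variance regression.* Per feature, the pooled mean of
normalised counts over all samples and the within-group pooled variance;
the shot-noise term μ·mean(1/factor) is subtracted to give the raw
variance, and a lowess curve of raw variance against log-mean is fitted
across features (`frac = 0.5`), clamped below at 0 and evaluated by
interpolation (constant beyond the observed range). With one sample per
group the within-group variance has no degrees of freedom; the variance
across all samples substitutes, which is what lets the downstream test
run with a single replicate per condition. Per-feature dispersions follow
as φ_g = max(0, w(μ_g))/μ_g².

## The conditional exact test

For one feature, let S₁ and S₂ be the group sums of (normalised) counts
and T = S₁ + S₂. Sums of n i.i.d. NB(r, p) variables are NB(n r, p), so
conditional on T the case sum follows
P(a) ∝ P(S₁ = a)·P(S₂ = T − a), a = 0…T. The two-sided p-value is the
total conditional probability of splits no more likely than the observed
one (with a 10⁻¹⁰ relative slack for floating-point ties). φ = 0 reduces
the conditional law to Binomial(T, n₁/(n₁+n₂)). For T > 10,000 the
enumeration is restricted to a ±12-standard-deviation window around the
conditional mean, always extended to include the observed split; the
neglected mass is below 10⁻¹², and a test pins the windowed result to the
full enumeration at the boundary. When the two groups share μ and φ the
conditional distribution is free of both — the implementation still
receives μ̂ (the pooled mean) to position the window.

Both exact-test pipelines are two-sided even though the generator's
effects are one-directional, because that is how the methods are used in
practice.

## The empirical-Bayes posterior

Two models per feature: M0, one shared NB mean for all samples; M1,
group-specific means. Priors are empirical: `prior_reps` (default 100)
draws, each taking method-of-moments estimates (group means; pooled
within-group moment dispersion) from randomly chosen features. Under M1
the case and control means come from *independent* features — M1 claims
the groups are unrelated, and this independence is what penalises it on
equivalently expressed features. Marginal likelihoods average the NB
likelihood over the prior draws.

The prior proportion of differential features and the per-draw weights
are estimated jointly by iterating posterior re-weighting: each draw is
weighted by the posterior that its source features follow that model
(product of the two source posteriors for M1, complement for M0), the
model proportion is the mean posterior, and the loop runs to a fixed
point (tolerance 10⁻⁸, capped at 2000 sweeps, warning on
non-convergence). Without the re-weighting the proportion estimate can
run away: M1 gains a spurious advantage on null features by fitting the
sampling split of their two group means. The reported p-value is
1 − posterior(M1); it is a posterior complement, not a frequentist
p-value, but is thresholded like one in the benchmark (as in practice).
At the fixed point the mean posterior equals the estimated proportion by
construction (`DEResult.de_proportion`).

## The other selectors

*Rank-sum.* Two-sided Wilcoxon rank-sum per feature. Groups of ≤ 8 per
side are tested by exact enumeration over all C(n, n₁) assignments of the
pooled midranks, two-sided by distance from the null mean — this handles
ties exactly and is pinned to a brute-force permutation oracle. Larger
groups use the tie-corrected normal approximation with continuity
correction (scipy). Features constant across all samples get p = 1.

*Lasso.* L1-penalised logistic regression on log₂(count+1), per-feature
standardised (penalised regression on raw counts is scale-pathological).
The inverse penalty is chosen by stratified 5-fold CV minimising the
binomial deviance over a 25-point grid; `one_se=True` switches to the
sparsest penalty within one standard error of the optimum. Selected =
nonzero coefficients.

*PSODT.* Binary particle swarm over feature-inclusion masks; fitness is
decision-tree accuracy under internal stratified 3-fold CV on the
training data. Defaults: swarm 50, 100 iterations, inertia 0.72,
cognitive = social = 1.49, sigmoid transfer. The per-feature score
counts, per iteration, membership in positions of particles whose
personal best coincides with the reigning global-best subset — one
reading of a scoring rule whose published description is ambiguous; it is
a choice, not an assertion of original intent. Selection uses the subset
the swarm converged to: features in the final global best of every
restart (default 3 restarts; `restart_consensus="half"` relaxes this).
Single-run swarm subsets are near-arbitrary ~50% masks; the cross-restart
consensus is what shrinks the selection to a small, stable set (≈ 12% of
features under exchangeable nulls), matching the wrapper's published
behaviour of low but stable sensitivity with high specificity.

*Random forest.* 500 trees, mtry = ⌊√n_features⌋ features per split
(using all features would remove the randomness the method depends on).
Importance is the canonical out-of-bag permutation form: per tree, the
decrease in OOB accuracy when one feature is permuted among the OOB
samples (features a tree never splits on contribute exactly 0), averaged
over trees and scaled by its standard error; scaled importance > 2
selects. Importance evaluated on training predictions is both masked by
correlated informative features and far slower, which is why the OOB form
is implemented directly.

## Evaluation

Sensitivity = TP/(TP+FN), specificity = TN/(TN+FP), with TP, FP, TN, FN
the *means over replications* of the per-replication confusion counts;
with fixed class sizes this equals the mean of per-replication rates.
Type-I error and power are rejection rates among noise and significant
features at the nominal level α = 0.05 and at the Bonferroni level
α/n_features (500 in simulation). Bonferroni rejection sets are subsets
of nominal ones by construction, and the identity checks run on every
emitted row. Per-replication method failures are logged and excluded from
that method's average. The published design uses 1000 replications; the
package defaults to that, the acceptance script uses 300 (rank-sum
scenarios) and 200 (exact-test pipelines), and the test suite 10–60 —
since sensitivity averages over 45 features per replication, the
Monte-Carlo standard error at 60 replications is already ≈ 0.005, an
order of magnitude inside every asserted tolerance.

## Classification

Repeated stratified 5-fold CV (stratification keeps the matched
case/control balance in every fold; 100 repeats by default). Feature
selection runs on the training folds only — corrupting a held-out fold
cannot change the training fold's selected set, and a test enforces this.
Inputs to classifiers are log₂(count+1) standardised with training-fold
statistics. Classifiers: logistic regression as near-unpenalised ML
(ridge 10⁻⁸, iteration-capped; non-convergence in the p ≫ n regime is
tolerated deliberately, because degrading rather than erroring is the
behaviour under study), RBF-kernel SVM with γ = 3 and soft-margin cost
C = 1 (an ε parameter belongs to the regression form of the SVM and is
accepted but ignored with a warning), and a 500-tree random forest. AUC
is the tie-corrected rank statistic; PPV/NPV come from hard decisions at
decision value 0/probability 0.5. An empty in-fold selection falls back
to the single best-scoring feature (logged).

## Itemset mining

Eligibility screen per cohort: a feature is a candidate "deregulated
item" if (a) some method's p-value passes Bonferroni, (b) it was selected
in ≥ 80 of the 100 CV repeats by at least one algorithm, and (c) at least
3 algorithms selected it at all. The frequency base of criterion (b) is
the classification stage's CV repeats — an inference, since the published
criteria do not name the base explicitly. Apriori mines all item sets
with support ≥ 0.5 level-wise with the downward-closure prune;
association rules A → B carry support(A∪B), confidence =
support(A∪B)/support(A), lift = confidence/support(B); defaults 0.5/0.5.
Transactions are cohorts, so a lift of 2 at confidence 1 pins the
consequent's support at one half — three of six cohorts. Both the miner
and the rule generator are pinned to exhaustive enumeration for universes
up to 15 items.

## Real-data loading

Count tables are features × samples TSV/CSV with integer cells and a
binary label row or sidecar. The only preprocessing is the
low-expression filter: features whose summed count over all samples is
*below* 10 are dropped (a total of exactly 10 is kept — the threshold is
read strictly), with removals logged. Matched designs are handled as
equal case/control counts; no paired test is implemented because the
compared methods are all unpaired.

## Known limitations

* The re-implementations target methodological fidelity, not numerical
  identity with the Bioconductor packages: quantile adjustment, Cox–Reid
  adjusted likelihoods and shrinkage priors are out of scope, so
  per-feature p-values will differ from those packages even where the
  benchmark-level rates agree.
* The PSODT scoring rule is one reading of an ambiguous description; its
  absolute selection rates should not be over-interpreted.
* The empirical-Bayes proportion estimate is a fixed point of a
  non-convex iteration; on data far from both the null and the baseline
  structure it can settle at different values across prior resamples.
* The simulator's independence and equal-library-size assumptions mean
  the benchmark says nothing about size-factor misestimation, correlated
  features or zero inflation on real data.
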