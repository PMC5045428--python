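# Methods

This note documents the models, estimators and numerical conventions of
`relapsesig`, the design choices made where the analysis recipe was
genuinely open, and what the synthetic cohorts do and do not emulate.

## The analysis model

The pipeline assumes a cohort of tumor expression profiles (genes ×
samples, continuous, e.g. RMA-normalized log2 microarray intensities) with
per-patient recurrence-free survival (RFS): the composite time to tumor
recurrence or death from any cause, right-censored at last follow-up. We
implement the conventional definition — event at recurrence/death, censored
otherwise — throughout.

**Standardization.** Arrays are Z-scored per sample: every column is
centred on its own mean intensity and scaled by its own SD (n−1
denominator), making arrays of different overall brightness comparable. A
per-gene mode exists behind `axis="gene"` but is not the default; the
per-array reading follows the "single experiment" convention of the
classical Z-score transformation for cross-dataset microarray comparison.
When input is probe-level, probes are averaged per gene (unweighted mean)
*before* standardization; for jitter-free synthetic data both orders
coincide (tested), and the order is exposed to callers by composing
`collapse_probes` and `zscore_standardize` explicitly.

**Discovery split.** Favorable = alive ∧ relapse-free ∧ follow-up strictly
> horizon (5 y); fatal = dead ∧ relapsed ∧ time strictly < horizon.
Patients exactly at the horizon are indeterminate and go to the testing
set — the conservative reading of the selection rule. The three sets
partition the cohort (property-tested).

**Differential screen.** Per-gene two-sample t-test, pooled-variance
Student by default (the classic microarray-era choice), Welch behind
`equal_var=False`. Bonferroni adjustment `min(1, m·p)` with strict
`p_adj < α` (α = 0.01). Genes with zero variance in both classes and equal
means get t = 0, p = 1, never significant; zero variance with distinct
means is treated as perfect separation (p = 0). Sample clustering uses
Euclidean distance with complete linkage, cut at k = 2; merge-distance ties
follow SciPy's deterministic observation-index ordering, and cluster labels
are Roman numerals in order of first appearance, so outputs are
reproducible for a fixed column order. The 2×2 cluster-vs-class chi-square
uses no continuity correction by default (flag available).

**Weighted voting.** Signal-to-noise S_i = (μ_r − μ_n)/(σ_r + σ_n) with
per-class sample SDs (n−1, consistent with standardization); boundary
b_i = (μ_r + μ_n)/2; vote V_i = S_i (e_i − b_i); relapse called when the
total vote over the top-N genes (|S| descending, ties by gene id) is
strictly positive. A total of exactly zero is called relapse-free — the
benign default. If σ_r + σ_n = 0, an epsilon (1e-12) is added with a
warning rather than producing ±∞, so degenerate fixtures cannot crash
cross-validation.

**Cross-validation and signature selection.** 5 folds × 100 repeats.
Folds are stratified: each class is shuffled separately and the two blocks
dealt round-robin, which bounds both the overall and per-class fold-size
imbalance by one and guarantees both classes in every training fold
(non-stratified assignment is available). One master seed spawns
per-repeat RNG streams (`numpy.random.SeedSequence`), so any repeat is
reproducible in isolation. The learning-error curve is
averageerror_N = (total misclassified over all 500 held-out folds)/100,
i.e. expected misclassified patients per repeat. The optimal N is the
smallest N with averageerror_N ≤ min + tolerance, tolerance 1.0 patients
by default — a deliberate parsimony formalization of "balance between
accuracy and signature size". The final signature counts, for each of the
500 training-fold rankings, which genes sat in its top-N; genes are ranked
by that frequency (ties by mean |S| rank across folds, then id). On
near-separable cohorts the error curve bottoms at ~0 early, so the
tolerance rule deliberately returns small signatures; callers who want a
signature of a fixed size (e.g. the familiar nine-gene panel) can pass
`signature_size` to the pipeline and the frequency ranking supplies the
top genes at that size.

**Risk score.** Weights are the *multivariate* Cox coefficients of the
signature genes fitted jointly on the discovery set (univariate fits are
reported alongside but never used as weights; the two differ whenever
genes are correlated). Cox fits use lifelines with Efron tie handling —
the accepted default, and material for synthetic data with tied times —
and Wald p-values; non-convergence (monotone likelihood under separation)
propagates as an explicit error. Risk Score = Σ Exp_i·w_i on standardized
expression; the cutoff is the median discovery score, frozen at fit time.
Group assignment: score > cutoff ⇒ high-risk; equality ⇒ low-risk.
Validation reuses the frozen weights and cutoff verbatim (bitwise,
tested); `assign` warns when input columns are far from zero mean, since
a transferred cutoff presumes the shared per-sample Z-score convention.
Multivariable adjustment codes covariates conventionally: age > 65 vs
≤ 65, male vs female, ever- vs never-smoker (unknown dropped), and stage
dummies against a stage-I reference row printed with HR 1.000.

**Survival evaluation.** Kaplan–Meier product-limit curves (lifelines)
with 3-/5-year rates read from the right-continuous step function at
exactly t = 3.0/5.0. Two-sided log-rank with the standard hypergeometric
variance, no continuity correction; stratified analyses skip strata below
a configurable minimum size (default 10) or with a single group level,
reporting the reason instead of a p-value. The time-dependent ROC at the
5-year horizon is the cumulative-case/dynamic-control estimator with
inverse-probability-of-censoring weights from the Kaplan–Meier estimate of
the censoring distribution (cases weighted by 1/G(T−), controls by
1/G(horizon)); AUC by trapezoid over the weighted staircase. With no
censoring before the horizon it reduces exactly to the rank-sum AUC of the
dichotomized outcome (tested), and it agrees with scikit-survival's
cumulative/dynamic AUC on censored data (cross-checked in tests).
Harrell's C is computed by explicit pair enumeration: usable pairs are
those whose time ordering is determined (earlier patient had an observed
event, including an event tied with the other's censoring time); score
ties count 0.5; the usable-pair count is reported. It matches lifelines'
concordance index to machine precision on tied, censored data (tested).

**Co-expression.** Per lncRNA, Pearson r against every candidate mRNA;
the top ⌈1%⌉ by r (positive-correlation ranking, ties by id) are its
partners, and the union across lncRNAs ("at least one") is the final
list. No variance pre-filter is applied; zero-variance candidates are
excluded with a warning because r is undefined for them.

## The synthetic cohort generator

No generative model is published for cohorts of this kind, so the
generator is an explicit stand-in built to exercise every assumption the
analysis makes:

- Latent class (relapse-prone) ~ Bernoulli(27.3%), the discovery-cohort
  relapse fraction.
- Expression: informative genes Normal(±effect/2, σ) by class — half
  shifted up (risky), half down (protective) — null genes Normal(0, σ);
  defaults: 200 genes, 9 informative, effect 2.0 σ-units, σ = 1.
- Survival: exponential with rate h₀·exp(Σ β_i x_i) over the informative
  genes (h₀ = 0.08/year; β defaults to 0.4·effect with each gene's shift
  sign, so effect 0 implies no survival link). The exponential law is the
  simplest one consistent with proportional hazards and gives closed-form
  oracles.
- Censoring: independent Uniform(0, 10 y) dropout plus administrative
  censoring at 10 years (non-informative).
- The observed relapse label is the realized composite event; a 55%
  fraction of eventful patients is additionally marked dead
  (`death_given_event`, matching the dead/relapsed ratio of the reference
  cohort), so the favorable/fatal selection rule yields discovery,
  testing and validation sets with realistic structure.
- Clinical covariates are drawn independently from the discovery-cohort
  marginals (76.9% age ≤ 65, 45.6% male, 76.9% stage I, 51.2%
  never-smoker).

What it does **not** emulate: raw CEL intensities, RMA artifacts, batch
effects, probe-level cross-hybridization, gene–gene correlation beyond
the class structure, informative censoring, or non-proportional hazards.
Passing tests therefore demonstrate correctness of the algorithms under
the stated model, not robustness to real-data pathologies.

## Problem sizes and calibration checks

The statistical tests run at sizes chosen to keep sampling error well
inside the asserted bands: type-I-error calibration of the t-screen on
1000 null genes; family-wise error over 20 null replicates; Cox CI
coverage of β = 0.8 over 200 replicates at n = 500 (asserted 95% ± 4%);
signature recovery of ≥ 8/9 informative genes in ≥ 9/10 seeds at effect
1.5, n = 121, 200 candidate genes; log-rank type-I error over 1000 label
permutations (asserted 0.05 ± 0.02); and the null C-index averaged over
score permutations on a 2000-patient cohort (asserted 0.5 ± 0.02).

## Known limitations

- No penalized or stepwise Cox, no proportional-hazards diagnostics, no
  competing-risks or restricted-mean extensions.
- The jackknife/leave-one-out alternative to repeated 5-fold CV is not
  provided; 5 × 100 was chosen for computational economy and is the
  convention this pipeline reproduces.
- The incident/dynamic time-ROC variant is out of scope; only
  cumulative/dynamic is implemented.
- Binary classification metrics are only meaningful for cohorts with
  resolved outcome labels; for testing-set patients with indeterminate
  short follow-up the pipeline reports survival metrics instead.
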