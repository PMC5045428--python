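# relapsesig

Discovery and validation of relapse-related gene-expression signatures for
lung adenocarcinoma (LUAD) cohorts.

More than 30% of LUAD patients relapse within five years of surgical
resection, and expression of long non-coding RNAs (lncRNAs) carries
prognostic information about who will. `relapsesig` implements, as a tested
and reusable pipeline, the classical analysis chain used to extract such a
signature from a gene-by-sample expression matrix with clinical follow-up:

1. **Extreme-outcome discovery split** — "favorable" patients (alive,
   relapse-free, followed beyond 5 years) vs "fatal" patients (dead with
   relapse within 5 years); everyone else forms an internal testing set.
2. **Differential screen** — per-gene two-sample t-tests with Bonferroni
   control (adjusted p < 0.01).
3. **Signal-to-noise weighted voting** — each candidate gene *i* gets a
   weight and a decision boundary

   S_i = (μ_relapse − μ_non-relapse) / (σ_relapse + σ_non-relapse),  b_i = (μ_relapse + μ_non-relapse) / 2,

   and a sample with expression *e_i* contributes votes
   V_i = S_i·(e_i − b_i) summed over the top-*N* genes by |S|;
   a positive total calls relapse. Stratified 5-fold cross-validation
   repeated 100 times yields the learning-error curve
   averageerror_N (misclassified patients per repeat), from which the
   optimal *N* and the frequency-based final signature are chosen.
4. **Cox risk score** — the signature genes are fitted jointly in a
   multivariate Cox proportional-hazards model on recurrence-free survival
   (RFS) and combined into Risk Score = Σ_i Exp_i·w_i; patients are split
   into high-/low-risk groups at the **median discovery score**, a cutoff
   frozen with the model and reused unchanged on every validation cohort.
5. **Survival evaluation** — Kaplan–Meier curves with 3-/5-year RFS rates,
   two-sided log-rank tests (plain and stratified by age/stage), the
   time-dependent ROC at a 5-year horizon (cumulative/dynamic, IPCW), and
   Harrell's concordance index.

A synthetic-cohort generator (`relapsesig.cohort`) reproduces the
statistical structure this analysis assumes — two latent classes, a small
set of informative genes, exponential proportional-hazards survival with
right censoring, realistic clinical covariate marginals — so the entire
pipeline is testable without any external download. A Pearson top-1%
co-expression module (`relapsesig.coexpr`) provides the mRNA partner lists
that feed downstream functional annotation.

## Worked example

```bash
relapsesig simulate --out demo/data --seed 29
relapsesig train --expr demo/data/expression.tsv \
                 --clin demo/data/clinical.tsv --out demo/run --seed 29
relapsesig report --run demo/run
```

prints (numbers produced by the run above):

```
# Relapse-signature discovery report

status: **ok**  |  seed: 29

- discovery split: 44 favorable + 21 fatal (testing n=56)
- differential genes (Bonferroni p < 0.01): 9
- optimal signature size N = 5
- signature: LNC0004, LNC0002, LNC0003, LNC0005, LNC0006
- discovery classification: accuracy 98.5%, sensitivity 95.2%, specificity 100.0%, AUC 0.999
- risk-score cutoff (discovery median): -2.5050

| dataset | n | log-rank p | AUC@horizon | C-index |
|---|---|---|---|---|
| discovery | 65 | 8.6e-09 | 0.999 | 0.950 |
| testing | 56 | 5.22e-08 | NA | 0.936 |
```

Reading this: of the 121 simulated patients, 65 extreme-outcome cases form
the discovery set; 9 genes survive the Bonferroni screen (the simulation
truly planted 9 informative genes); the cross-validated error curve selects
a 5-gene voting model that classifies the discovery set almost perfectly;
and the Cox risk score built on those genes separates RFS sharply in both
the discovery and held-out testing sets (log-rank p ≈ 1e-8, C ≈ 0.94). The
testing-set ROC is reported NA because that set happens to contain no
patient still event-free beyond the 5-year horizon — the favorable/fatal
rule removed them into discovery. Validating the frozen model on a fresh
150-patient cohort from the same generative truth:

```bash
relapsesig simulate --out demo/external --seed 30 --n-patients 150
relapsesig validate --model demo/run --expr demo/external/expression.tsv \
                    --clin demo/external/clinical.tsv --out demo/val
# validation: n=150, log-rank p=1.14e-16, C-index=0.955
```

The same workflow is available as a library — `run_discovery` /
`run_validation` in `relapsesig.pipeline`, with the two fitted models
exposed as model/results pairs (`WeightedVoting(...).fit()`,
`CoxRiskScore(...).fit()`), each with a `summary()`.

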