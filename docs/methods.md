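# Methods

This note documents the statistical model, the synthetic-cohort generator, the
numerical conventions, and the design decisions behind `imtrisk`, in enough
detail to audit or re-derive any of them.

## 1. Risk-class construction

A continuous phenotype vector (baseline IMT, follow-up IMT, or their
difference) is reduced to a binary problem at tail fraction q ∈ (0, 0.5):
the floor(q·n) smallest values form the low-risk class and the floor(q·n)
largest the high-risk class; everyone else is excluded. The pooled
distribution is used — no age or sex stratification. Class membership is
rank-based (stable sort by value, then subject order), so it is invariant
under strictly increasing transforms of the phenotype and deterministic under
ties: subjects strictly beyond a cutoff enter first, cutoff-equal subjects are
admitted in stable subject order until the target count is reached. Cutoff
*values* are the empirical q and 1−q quantiles (linear interpolation between
order statistics); they are what gets frozen and applied to an independent
cohort (`QuantileRiskStratifier.transform`), where labeling is by value
comparison, not re-quantiling. An optional guard re-excludes subjects whose
value lies within δ (default 0.02 mm) of the nearer cutoff, since extreme-class
membership near the boundary is sensitive to measurement error.

Progression classes are built on the raw change (follow-up − baseline), not
percent change. Subjects missing either visit are dropped with a logged count.

## 2. The classifier

`MixedNaiveBayes` implements the posterior
P(R|P) ∝ P(R) · ∏ P(P_i | R). Choices:

- **Priors** proportional to training class counts (normalization is forced by
  the probability axioms and does not change the argmax).
- **Categorical features** (genotypes, binary CRFs): Laplace smoothing with
  α = 1. Zero-frequency genotypes are common at class sizes of 50–250, and a
  hard zero would veto the whole product. Genotype columns should declare
  their three levels (`categories={snp: (0,1,2)}`) so an absent homozygote
  still gets probability α/(n_c + 3α); a level never declared falls back to
  the same floor.
- **Numeric features**: per-class Gaussians. The SD is floored at
  1e-3 × (class-pooled feature SD, or 1 if that is zero) to keep densities
  finite for near-constant features.
- **Genotypes are unordered categories**, not allele dosages: the model
  factorizes over SNPs without an additivity assumption, matching the 2×3
  (genotypic) association test used in the comparison arm.
- All likelihoods are accumulated in log space; the class-independent scaling
  constant cancels on normalization. Ranking by the high-class posterior is
  what the ROC uses; the posterior values themselves tend to be extreme
  (a known artifact of the independence assumption) but their order is what
  matters for AUC.
- Exact posterior ties classify as low risk (documented tie rule).

The model serializes to JSON (priors, tables, Gaussian parameters, feature
list) for the frozen-model validation workflow.

**Scoring contract.** The per-feature log-likelihood matrix is exposed
(`feature_log_likelihood`) because the naive factorization makes any feature
subset's joint log-likelihood an exact row sum. The wrapper search and all
deletion scores exploit this: one model fit per fold serves every subset, and
a successor subset's score is the parent's minus one row. Before ranking,
log-posterior margins are quantized to 1e-9 so that subjects with identical
profiles tie exactly regardless of which algebraically equivalent path
produced the sum (direct summation leaves different ~1e-16 residue than
parent-minus-feature; with heavily tied categorical scores that residue would
otherwise change the midrank AUC).

## 3. Feature selection

**Filter.** Information gain IG = H(class) − Σ_v p(v) H(class|v) in bits,
computed per feature; numeric features are first discretized by supervised
entropy minimization with the MDL acceptance rule (a split is kept only when
its gain exceeds (log2(N−1) + log2(3^k−2) − k·H(S) + k1·H(S1) + k2·H(S2))/N).
A feature whose discretization collapses to one bin has zero gain. The top
k = 40 features (ties broken by name) proceed to the wrapper. With
`force_crfs` (the default in the pipeline), only SNPs are filtered and
searched; the CRFs are part of every model.

**Wrapper.** Best-first search in the backward direction over subsets of the
40 candidates. Every state is scored by the mean stratified 5-fold CV AUC of
the classifier, under one fold split fixed per search invocation so scores are
comparable across states. The open list is a max-heap on score (backtracking);
each state enters it at most once. Termination: `stall_limit` (default 5)
consecutive expansions without improving the incumbent, or `max_expansions`
(default 100) expansions — the second bound is needed because on noisy or null
data chance improvements can otherwise sustain the search indefinitely; with
both set to None the search provably enumerates every subset (the
exhaustive-oracle test runs it that way). Tie rule for the returned optimum:
higher score, then smaller subset, then lexicographic feature order — the
"minimal informative set" convention. The full search trace (every subset
visited with its score) is retained and replayable.

**Significance arm.** SNPs with Bonferroni-corrected exact genotypic p ≤ α
(default 0.05, m = number of SNPs tested).

## 4. Assessment

- **AUC**: Mann–Whitney form with midrank ties; verified against the exact
  U statistic and against enumerated score pairs.
- **Outer CV**: stratified k = 10 folds; the reported accuracy is the mean of
  per-fold AUCs (pooled out-of-fold AUC is available as a secondary output).
  Folds are reduced, with a warning, when a class has fewer than k subjects.
- **Two evaluation modes.** `fixed_features` evaluates a given panel;
  `reselect_per_fold` re-runs the entire filter–wrapper inside every training
  fold, so selection never sees held-out subjects. The fixed-panel mode
  mirrors the arm-comparison design in which a panel is selected once (its
  inner 5-fold CV guarding against selection bias) and then cross-validated;
  it retains optimism because selection saw all labeled subjects. Measured on
  synthetic cohorts with three weak planted SNPs (q = 0.15, n = 1000), the
  fixed-panel predictive arm scores ≈ +0.07 AUC over CRFs alone, the fully
  nested mode ≈ −0.05 (the wrapper keeps ~20–25 noise SNPs of 40 candidates
  at these class sizes, and even the ideal 3-SNP panel only adds ≈ +0.018).
  The randomized-label null — which uses the nested mode — is the
  corresponding honesty check: its AUC stays at 0.5.
- **Deletion contributions**: ΔAUC = AUC(panel) − AUC(panel minus feature),
  with the reduced model refit, both under one shared fold split per report so
  differences reflect the deletion alone. Negative values are reported raw but
  floored at zero for the percent-contribution column, which normalizes over
  the SNP set to sum to 100.
- **Interaction score** I(x,y) = ΔAUC_{x,y} − ΔAUC_x − ΔAUC_y, symmetric by
  construction. Two estimator properties matter for interpretation: (i) AUC
  concavity gives *any* pair of informative features a small positive bias
  (single deletions cost less than half the joint deletion), so I should be
  compared against additive pairs of matched marginal contribution rather than
  against zero; (ii) at class sizes below ~300 per class the fold-level noise
  exceeds typical planted-interaction signals, so the package estimates I by
  averaging over repeated fold splits (repeated CV) when power matters. The
  epistasis-recovery test operates at n = 2000, q = 0.15, amplitude d = 1.0,
  five fold splits — conditions chosen by simulation so a planted
  marginal-null interaction is detected (I > 0) in ≥ 80% of runs while a
  contribution-matched additive pair stays centered at zero.
- **Randomized null**: repeatedly draw random low/high subject sets of the
  real class sizes, run the nested pipeline, record mean AUC; the average over
  ≥ 100 repetitions concentrates at 0.5 and the maximum is retained so a real
  model can be compared against the best random one.
- **Independent validation**: new subjects (disjoint IDs enforced) are labeled
  by the frozen cutoffs and scored by the frozen model; the AUC and its drop
  versus the training estimate are reported.

## 5. Synthetic cohort generator

The generator defines the package's study conditions; its defaults are fixed
and tests run at them.

- **Genotypes**: each SNP i.i.d. at Hardy–Weinberg proportions
  ((1−p)², 2p(1−p), p²); the default panel has 108 SNPs with MAF ~ U(0.1, 0.5)
  drawn once reproducibly, the first 17 flagged as the established-marker
  panel analog. No linkage disequilibrium or population structure.
- **Risk factors**: independent draws matching published baseline marginals —
  e.g. age 31.7 (SD 4.92) years, BMI 25.2 (4.38) kg/m², 55.3% women, 22.8%
  smokers. Binary factors are Bernoulli, numeric factors Gaussian.
- **Baseline IMT**: intercept + linear CRF term + SNP main-effect shifts +
  centred log-normal residual (σ_log = 0.4), scaled so the marginal is
  mean 0.58 mm, SD 0.09 mm, with mild right skew — IMT distributions in
  general populations are positively skewed. CRF coefficients are derived
  from the published *marginal* correlations (coef = r·σ_IMT/σ_CRF) and then
  attenuated by 0.63: real risk factors are strongly inter-correlated, so
  reproducing each marginal r with independent simulated factors would
  overstate the joint CRF signal; the attenuation is calibrated so the
  CRF-only classifier operates at its published accuracy (10-fold CV
  AUC ≈ 0.74 between the 15% extreme baseline classes).
- **Follow-up IMT**: baseline latent + mean progression 0.06 mm + SNP
  progression shifts + 3×3 epistatic table lookups + waist/ApoB progression
  terms + innovation noise whose scale is solved in closed form from the
  sample moments so the realized correlation between *observed* baseline and
  follow-up matches the target (default r = 0.582, the published
  between-visit correlation).
- **Measurement error**: multiplicative, value × (1 + cv·ε) with cv = 0.064
  (the published between-visit coefficient of variation). Observed values are
  floored at 0.01 mm (IMT is a thickness).
- **Epistasis construction**: `multiplicative_epistasis_table(maf_a, maf_b, d)`
  returns d·outer(u, v) with u = 1[g=2] − P(g=2) under HWE; every row and
  column mean is exactly zero, so the pair has provably null marginal effects
  while the double-homozygote cell carries shift d·(1−p²)². Calibrations used
  by the tests: a per-allele baseline shift of 0.0125 mm yields single-SNP
  10-fold CV AUC ≈ 0.58 between the 15% extreme classes; d = 1.0 on
  progression is the demonstrated-recoverable interaction amplitude.
- **Missingness**: MCAR at configurable entry rates for genotypes and
  follow-up phenotype; enough to reconstruct the complete-case /
  held-out-validation split design.

What the generator does **not** emulate — and hence what passing tests do not
establish about real cohorts: linkage disequilibrium (selection among
correlated SNPs is harder than among independent ones), CRF inter-correlation
beyond the global attenuation, age/sex structure in the phenotype tails,
genotyping error, and informative missingness.

## 6. Exact genotypic test and supporting statistics

The 2×3 exact conditional test fixes both margins and enumerates the table
space over its two free cells; the p-value is the sum of multivariate
hypergeometric probabilities of all tables whose point probability is at most
the observed one (Fisher's ordering — two-sided by construction), computed via
log-gamma with a 1e-7 relative slack on the log scale so genuinely tied tables
are never excluded by round-off. Degenerate margins (an empty row, or a single
occupied column) return p = 1. The implementation always enumerates — feasible
at cohort scale since the grid is (c0+1)×(c1+1) — and is tested against an
exact rational-arithmetic oracle and a 10⁵-permutation Monte-Carlo null.
Bonferroni correction multiplies by the number of tests and truncates at 1.
The Pearson r test (t on n−2 df) and the two-sample Kolmogorov–Smirnov D
statistic delegate to scipy, with input validation matching their contracts.

## 7. Problem sizes used by the test suite and acceptance script

Cohorts of 1000 subjects × 108 SNPs (2000 for the epistasis power check),
20 randomizations per risk class for the null sweep (100 total), 20 seeded
runs for recovery rates, 10⁵ permutations for the Monte-Carlo oracle. The
full suite runs in ~3 minutes and the acceptance script in ~2 minutes on one
CPU; all randomness derives from explicit seeds, and every reported quantity
is recomputed at run time.

## 8. Known limitations

- The interaction score inherits the biases described in §4; it is a screening
  statistic, not a calibrated test of epistasis.
- The wrapper's inner-CV AUC is a maximum over many visited subsets and is
  therefore optimistic; only the outer CV (and preferably the nested mode or
  an independent validation set) estimates generalization.
- Naive Bayes cannot represent class-conditional dependence between features;
  interactions are detectable only through the marginal enrichment they induce
  in the extreme classes.
- The exact test conditions on both margins; alternatives that condition on
  one margin would give different (typically less conservative) p-values.
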