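# Methods

This note documents the statistical models, the synthetic benchmark,
and the numerical and design choices behind `cerna-net`.

## The ceRNA pair model

The competing-endogenous-RNA hypothesis holds that transcripts sharing
miRNA response elements titrate a common miRNA pool and therefore
co-vary positively. The pair screen operationalizes this with two
independent pieces of evidence:

* **Shared regulators.** Given miRNA→mRNA and miRNA→lncRNA interaction
  tables, the miRNA universe is their intersection (`Total` miRNAs);
  each gene's regulator set is clipped to it. For a pair with set
  sizes N_m, N_ℓ and overlap k, the p-value is the upper tail of the
  hypergeometric distribution P(X ≥ k | Total, N_m, N_ℓ). The sum is
  accumulated in log space (gammaln + logsumexp) so deep tails keep
  relative precision; genes whose clipped set is empty get overlap 0
  and p = 1 without special-casing. The screen keeps pairs with
  p < `hyper_alpha` (default 0.05, strict).
* **Positive co-expression.** The Pearson correlation of each candidate
  pair is computed across all samples of the contrast (both groups
  pooled; a per-group variant is exposed via configuration). The
  retention threshold is the `pcc_percentile`-th percentile (default
  95, linear interpolation between order statistics) of the candidate
  pairs' correlation distribution, including negative values, and the
  rule is PCC > max(threshold, 0), strict. The realized threshold is
  data-dependent and always reported. Whether the percentile
  population should be the step-1 candidates or all SDE lncRNA×mRNA
  pairs is genuinely ambiguous in the literature this follows;
  candidates is the default, `pcc_population="all"` selects the
  alternative.

Because the threshold is a percentile of the candidate distribution,
the retained set is by construction roughly the top 5% of candidates;
a planted signal can only be recovered cleanly when true pairs are a
comparable fraction of the candidates and separated from the null
correlation bulk (see benchmark below).

## Moderated t-test

Two-group means model only (the designs this package targets are
two-group contrasts); no covariates. Per-gene pooled residual
variances s²_g with d_g = n₀+n₁−2 follow s²_g|σ²_g ~ σ²_g·χ²_{d_g}/d_g
with a scaled inverse-chi-square prior (d₀, s₀²). Hyperparameters are
estimated by moment matching on e_g = log s²_g − ψ(d_g/2) + log(d_g/2):
the sample variance of e in excess of ψ′(d_g/2) estimates ψ′(d₀/2)
(trigamma inverted by Newton iteration), and
log s₀² = ē + ψ(d₀/2) − log(d₀/2). When the excess is non-positive,
d₀ = ∞ and s₀² is the geometric-mean pooled variance; the moderated
statistic is then referred to the standard normal, otherwise to a t
distribution on d₀+d_g df. Zero-variance genes are floored at 1e−12
before the log. Selection uses raw p-values (the thresholds 0.01/0.05
are part of the procedure being reproduced); Benjamini–Hochberg
q-values are reported for transparency but never drive selection. The
implementation is cross-checked in the test suite against Bioconductor
limma (hyperparameters, t, p agree to ≤1e−4 relative).

## Network statistics

Hubs are the top-5% degree nodes with k = ⌈fraction·n⌉ and all degree
ties at the cutoff included — published hub counts from this family of
analyses are consistent with ceiling-plus-ties but the exact historical
rule is unknowable, so ours is simply documented and deterministic.
"Right-skewed degree distribution" is operationalized as positive
sample skewness. The lncRNA-vs-mRNA degree comparison uses the exact
Wilcoxon rank-sum null when n ≤ 20 without ties, otherwise a normal
approximation with tie correction and a continuity correction shrunk
toward the null mean (identical samples give p = 1 exactly).

## Module detection

Historical analyses clustered the network incidence matrix visually
(city-block distance, complete linkage) and read modules off the
heatmap. This is formalized as: agglomerate the binary lncRNA rows
with exactly that metric/linkage, breaking distance ties by merging
the lexicographically smallest cluster pair (results become
permutation-invariant up to this rule); cut at k (default 3, exposed);
assign each mRNA to the cluster holding the majority of its edges,
ties resolved by its highest-degree partner then id order. Binary
incidence values, not expression profiles, are clustered. The
clusterer agrees with `scipy.cluster.hierarchy` complete linkage on
tie-free data (verified in tests); optimal-k selection is out of scope.

## Biomarker panel selection

* Random-forest elimination uses an explicit bagged ensemble of CART
  trees (default 300, `max_features="sqrt"`): per tree, the
  out-of-bag samples score a baseline accuracy, each feature is
  permuted once on the OOB block, and the importance is the mean
  accuracy drop. Each round discards max(1, ⌊k/3⌋) lowest-importance
  features (ties broken by feature id) until ≤ `target_k` remain
  (defaults 7 occurrence-style, 6 recurrence-style). The published
  stopping rule "balance accuracy against panel size" has no formula;
  a fixed target is the deterministic stand-in.
* All 2^k−1 subsets (guarded at k ≤ 20) are evaluated by LOOCV with an
  RBF SVM, C = 1, gamma = 1/(n_features·Var(X)) (the libsvm default
  family), solver tolerance 1e−6 for order-stable decision values. Standardization is fit on each training fold only — no
  leakage. Held-out decision values, not hard labels, feed the ROC;
  AUC is Mann–Whitney U/(n₁n₀) with half-credit for ties. A training
  fold reduced to one class predicts that class and is flagged.
* Caveat: under strong class imbalance (e.g. 5 vs 22), null LOOCV
  accuracy concentrates near the majority-class rate (22/27 ≈ 0.81),
  so accuracy alone overstates performance; the pipeline flags such
  runs and AUC should be read alongside.

## Synthetic benchmark

The generator emulates the statistical structure the pair screen
assumes, not microarray physics:

* Two-group log2 expression, baselines Uniform(6, 12), Gaussian noise
  (`noise_sd` = 1), differential genes shifted by ±`effect_size`
  (default 2) in group 1; 25 vs 25 samples by default.
* miRNA universe of 200; per-gene regulator sets of
  Poisson-distributed size (mean `per_gene_targets` = 15) drawn
  uniformly. Planted structure comes in `n_blocks` = 3 blocks of
  2 lncRNAs × 6 mRNAs: each block owns a disjoint miRNA core of size
  `shared_k` = 10 contained in every member's set, with the remaining
  miRNAs of planted mRNAs drawn outside the union of their block
  lncRNAs' sets — so every planted pair overlaps in *exactly*
  `shared_k` miRNAs by construction. All 12 pairs per block are
  planted (36 total).
* Co-expression by a shared latent factor per block:
  residual = √ρ·z_block + √(1−ρ)·ε, giving within-group pair
  correlation ρ (default 0.9) exactly in expectation; block members
  share the differential sign, so the pooled correlation is higher
  (≈0.95 at the defaults) while unrelated same-sign differential genes
  pool to ≈0.5 — the gap the percentile threshold must resolve.
* Differential-gene counts (1185 of 1600 mRNAs, 24 of 40 lncRNAs,
  planted genes always included) were chosen analytically so that the
  36 planted pairs are ≈5% of the expected step-1 candidates: with the
  exact null candidate rate of the discrete hypergeometric screen at
  these set sizes (0.0237), expected candidates ≈ 36 + 0.0237·28,700
  ≈ 715. This mirrors the top-5% retention rule: the planted fraction
  matches the retained fraction, so full recovery with few false
  pairs is achievable rather than arithmetically impossible.
* What the generator does **not** model: probe-level effects,
  batch/array structure, miRNA expression (never used by the
  procedure), heavy-tailed noise, correlated null genes. Passing the
  recovery benchmarks therefore demonstrates correctness of the
  machinery under the stated model, not performance on real arrays.

A null configuration (nothing planted, zero effect, near-full miRNA
universe) calibrates type-I behaviour. Note that the hypergeometric
screen is a discrete test: its achievable size at α = 0.05 is ≈0.024
with these set sizes, not 0.05. Calibration is therefore asserted
against the *exact* achievable size computed from the realized set
sizes (always ≤ α), while the continuous moderated-t false-positive
rate is asserted at the nominal level.

## Problem sizes and determinism

Default experiments run a 1640-gene × 50-sample matrix, ≈29,000 pair
tests per seed, 10 recovery seeds and 50 calibration seeds — sizes
chosen so the complete validation suite executes in about a minute on
one core while leaving every statistical conclusion comfortably inside
its tolerance. All randomness flows from explicit seeds
(`numpy.random.default_rng` with derived seed sequences); identical
configurations produce bit-identical outputs, and the pipeline
manifest records seeds, thresholds and input checksums.

## Known limitations

* Experimentally supported interaction tables are incomplete and
  biased; the screen inherits that bias (credibility over coverage).
* The pooled-sample PCC conflates within-group co-regulation with the
  shared differential shift; the per-group option isolates the former.
* Degree-based hubs and k-cut modules are descriptive, not inferential.
* LOOCV on exhaustively searched subsets is optimistically biased;
  external validation data is required for honest panel performance.
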