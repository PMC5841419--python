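# cerna-net

Inference of **dysregulated lncRNA–mRNA networks under the ceRNA
hypothesis**: long non-coding RNAs and mRNAs that compete for shared
microRNAs regulate each other indirectly, so a disease-associated
lncRNA–mRNA pair should (i) share significantly more miRNA regulators
than chance and (ii) be positively co-expressed. `cerna-net` turns
two-group expression profiles (e.g. patients vs controls, or relapse vs
no relapse) and experimentally supported miRNA-target tables into
competing-pair calls, a bipartite lncRNA–mRNA network with hub and
module structure, gene-set enrichment of the network mRNAs, and an
lncRNA biomarker panel — with a synthetic-data generator that plants
known ceRNA structure so every stage can be validated against ground
truth.

It is aimed at computational biologists who want a tested, scriptable
version of this widely used multi-step analysis rather than a chain of
one-off scripts.

## Method

1. **Differential expression.** Genes are tested with an
   empirical-Bayes moderated t-statistic. Per-gene variances
   s²_g (d_g = n₀+n₁−2) are shrunk toward a prior (d₀, s₀²) fitted by
   moment matching on log s²_g:

       s̃²_g = (d₀·s₀² + d_g·s²_g) / (d₀ + d_g),
       t_g = (x̄₁ − x̄₀) / (s̃_g · √(1/n₀ + 1/n₁)),  df = d₀ + d_g.

   Genes with raw p below the contrast threshold (0.01 occurrence-style,
   0.05 recurrence-style) are called significantly differentially
   expressed (SDE).

2. **Competing pairs.** For each SDE lncRNA ℓ and SDE mRNA m, with
   N_m and N_ℓ their miRNA-set sizes inside the universe of `Total`
   miRNAs common to both interaction tables and k the observed shared
   count, the cumulative hypergeometric p-value is

       p = Σ_{i=k}^{min(N_m, N_ℓ)} C(N_m, i)·C(Total−N_m, N_ℓ−i) / C(Total, N_ℓ),

   computed in log space. Pairs with p < 0.05 are candidates; the
   Pearson correlation (PCC) of each candidate is computed across all
   samples and pairs above max(95th percentile of the candidate PCC
   distribution, 0) are retained. The realized threshold is a reported
   output, not a constant.

3. **Network, hubs, modules.** Retained pairs merge into a bipartite
   network; degree statistics per class, a Wilcoxon rank-sum test of
   lncRNA vs mRNA degrees, and the top-5% degree nodes (ties included)
   as hubs. Modules come from complete-linkage/city-block hierarchical
   clustering of the binary incidence matrix, cut at k (default 3),
   with each mRNA assigned to the lncRNA cluster holding most of its
   edges.

4. **Enrichment.** Upper-tail hypergeometric overrepresentation of the
   network mRNAs against user-supplied GMT gene sets.

5. **Biomarker panel.** Iterative random-forest elimination (discard
   the max(1, ⌊k/3⌋) least important features by out-of-bag permutation
   importance per round) down to ≤ k features, then exhaustive 2^k−1
   subset evaluation with an RBF-SVM under leave-one-out
   cross-validation; the panel with the highest LOOCV accuracy wins
   (ties: higher AUC, fewer features).

## Worked example

```python
import cerna_net as cn

cfg = cn.SyntheticConfig(seed=3)          # 25 vs 25 samples, 36 planted pairs
mm, ml, truth, expr, labels = cn.generate_dataset(cfg)

table, sde, summ = cn.run_de(expr, labels, p_threshold=0.01)
u = cn.build_universe(mm, ml)
screen = cn.identify_competing_pairs(
    sde[sde.gene_class == "mRNA"].index,
    sde[sde.gene_class == "lncRNA"].index, u, expr)
net = cn.build_network(screen.retained)
```

prints (via the calls shown in `scripts/` and the CLI):

```
SDE genes: 1196 mRNAs, 24 lncRNAs
shared-miRNA universe: 194 miRNAs
candidates: 710, retained: 36, PCC threshold: 0.824
network: 24 nodes / 36 edges
mean degree mRNA 2.0, lncRNA 6.0, Wilcoxon p = 2.02e-06
module 0: 2 lncRNAs, 6 mRNAs, 12 internal edges   (x3 modules)
best panel: ('LNC-0014', 'LNC-0016', 'LNC-0017', 'LNC-0026'),
LOOCV accuracy 0.980, AUC 1.000
```

Reading: of 710 lncRNA–mRNA pairs that share more miRNAs than chance,
the top-correlated 36 (PCC > 0.824, the realized 95th-percentile
threshold) are exactly the 36 planted pairs; the three planted blocks
are recovered as modules, and a 4-lncRNA panel separates the groups
almost perfectly. The same analysis runs from the shell:

```bash
cerna-net simulate --seed 3 --out data/
cerna-net run --config pipeline.yaml
```

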